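"""Classify previously unseen cells with a fitted morphotype tree.

The decision tree distils the clustering into five threshold rules
(span ratio, circularity, hull area, then one sub-type cut per cluster),
so any measured cell can be assigned a morphotype without re-running the
cluster analysis.  Here the tree fitted on one cohort classifies a fresh
cohort; the distribution report shows the reactive morphotype (Cluster 4)
concentrating in the treated strata.
"""

from gliamorph import default_cohort, generate_cohort
from gliamorph.tree import classify_table, distribution_report
from gliamorph.workflow import PipelineConfig, measure_cells, run_pipeline

trained = run_pipeline(default_cohort(seed=42, scale=0.4), PipelineConfig(seed=42))

fresh_spec = default_cohort(seed=7, scale=0.25)
fresh_cells, fresh_meta = generate_cohort(fresh_spec)
fresh_features = measure_cells(fresh_cells, seed=7)

labels = classify_table(fresh_features, trained.tree)
print(labels["type"].value_counts().sort_index().to_string())

report = distribution_report(labels, fresh_meta, level="cluster")
print("\npercent of cells per cluster within each stratum:")
print(report.to_string(index=False))
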