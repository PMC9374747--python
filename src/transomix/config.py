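"""Pipeline configuration with the study's published thresholds as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class PipelineConfig:
    """Tunable thresholds of the trans-omic pipeline.

    Defaults mirror the published analysis: a molecule is glucose-responsive
    when q <= 0.1 and \\|log2 fold change\\| >= 0.585 (2**0.585 = 1.5-fold) at
    any post-bolus time; responses are rapid below 20 min and slow above
    60 min; motif enrichment is tested on clusters of >= 100 genes at
    q <= 0.1; pathway association uses q <= 0.01 and the top-10% coverage
    rule; condensation keeps metabolite->pathway edges covering >= 5
    reactions and TFs regulating >= 5 reactions; regulation summaries list
    regulators hitting more than 15 reactions.
    """

    fc_threshold_log2: float = 0.585
    q_threshold: float = 0.1
    rapid_max_min: float = 20.0
    slow_min_min: float = 60.0
    min_detected_fraction: float = 0.5
    min_cluster_size_for_enrichment: int = 100
    enrichment_q: float = 0.1
    pathway_assoc_q: float = 0.01
    top_fraction_pathways: float = 0.10
    min_reactions_per_condensed_edge: int = 5
    min_reactions_per_tf_node: int = 5
    display_min_reactions_top_regulators: int = 15
    random_seed: int = 0
    # -- documented secondary switches --------------------------------------
    #: number of clusters used when cutting the metabolite dendrogram
    n_metabolite_clusters: int = 8
    #: q-value pooling scope: "per_time" (default) or "pooled" across times
    qvalue_pooling: str = "per_time"
    #: comparator for the child-cluster exclusion rule: "odds_ratio" or "p"
    enrichment_comparator: str = "odds_ratio"
    #: basis of the >=5 TF rule in condensation: "reactions" or "enzymes"
    tf_min_basis: str = "reactions"
    #: registered count-test method for the gene layer
    count_test_method: str = "welch_log2"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("q_threshold", "enrichment_q", "pathway_assoc_q"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if not 0 < self.top_fraction_pathways <= 1:
            raise ValueError("top_fraction_pathways must lie in (0, 1]")
        if not self.rapid_max_min < self.slow_min_min:
            raise ValueError("rapid_max_min must be below slow_min_min")
        if not 0 <= self.min_detected_fraction <= 1:
            raise ValueError("min_detected_fraction must lie in [0, 1]")
        if self.qvalue_pooling not in ("per_time", "pooled"):
            raise ValueError("qvalue_pooling must be 'per_time' or 'pooled'")
        if self.enrichment_comparator not in ("odds_ratio", "p"):
            raise ValueError("enrichment_comparator must be 'odds_ratio' or 'p'")
        if self.tf_min_basis not in ("reactions", "enzymes"):
            raise ValueError("tf_min_basis must be 'reactions' or 'enzymes'")

    # ---- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
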