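"""Core domain containers for multi-omic time-course data and knowledge tables.

The study design emulated throughout the package is an oral glucose tolerance
time course in two mouse genotypes (lean wild-type ``WT`` and leptin-deficient
obese ``OB``): molecules are sampled at fixed minutes after the glucose bolus,
with the 0-min fasting sample as the within-genotype baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "OB")
LAYERS = ("metabolite", "gene", "phospho")

TF_MODES = ("activator", "repressor", "unknown")
ALLOSTERIC_MODES = ("activator", "inhibitor")
PATHWAY_CLASSES = ("carbohydrate", "lipid", "amino_acid", "other")


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an on-disk table cannot be parsed."""


class IntegrityError(ValueError):
    """Raised when knowledge tables cross-reference unknown identifiers."""


@dataclass
class OmicsTimeCourse:
    """Replicate-level abundances for one omic layer.

    ``data`` is molecules x samples, with a three-level column MultiIndex
    ``(genotype, time, replicate)``.  Missing measurements are NaN, never 0:
    a zero is a real measured abundance, a NaN is a non-detection.
    """

    layer: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ---- structure -------------------------------------------------------

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genotypes(self) -> list[str]:
        return sorted(
            self.data.columns.get_level_values(0).unique(),
            key=lambda g: GENOTYPES.index(g),
        )

    @property
    def time_points(self) -> list[int]:
        return sorted(int(t) for t in self.data.columns.get_level_values(1).unique())

    def replicate_counts(self) -> pd.Series:
        """Number of replicate columns per (genotype, time)."""
        return self.data.columns.to_frame(index=False).groupby(
            ["genotype", "time"], sort=True
        ).size()

    # ---- access ----------------------------------------------------------

    def replicate_values(self, molecule: str, genotype: str, time: int) -> np.ndarray:
        """All replicate values (NaN included) for one molecule/genotype/time."""
        return self.data.loc[molecule, (genotype, time)].to_numpy(dtype=float)

    def block(self, genotype: str, time: int) -> pd.DataFrame:
        """molecules x replicates slice for one genotype and time."""
        return self.data.xs((genotype, time), axis=1, level=(0, 1))

    def mean_traces(self, genotype: str) -> pd.DataFrame:
        """Replicate-averaged trace per molecule (molecules x times).

        Means are arithmetic over non-missing replicates on the raw scale.
        """
        sub = self.data[genotype]
        means = sub.T.groupby(level="time").mean().T
        means.columns = [int(t) for t in means.columns]
        return means[sorted(means.columns)]

    def subset(self, molecules) -> "OmicsTimeCourse":
        return OmicsTimeCourse(self.layer, self.data.loc[list(molecules)])

    # ---- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 3:
            raise ValidationError("columns must be a (genotype, time, replicate) MultiIndex")
        self.data.columns = cols.set_names(["genotype", "time", "replicate"])
        for g in cols.get_level_values(0).unique():
            if g not in GENOTYPES:
                raise ValidationError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")
        times = self.time_points
        if 0 not in times:
            raise ValidationError("time points must include the 0-min fasting baseline")
        if any(t < 0 for t in times):
            raise ValidationError("time points must be non-negative minutes")
        values = self.data.to_numpy(dtype=float)
        neg = np.nan_to_num(values, nan=0.0) < 0
        if neg.any():
            bad = self.data.index[neg.any(axis=1)][0]
            raise ValidationError(f"negative abundance for molecule {bad!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate molecule id {dup!r}")


@dataclass
class KnowledgeBase:
    """Regulatory-connection tables emulating KEGG/BRENDA/TRANSFAC content.

    All maps use opaque string identifiers; reactions are keyed by EC-number
    style strings and may be shared by several enzyme genes (many-to-many).
    """

    enzyme_reactions: dict[str, set[str]] = field(default_factory=dict)
    reaction_substrates: dict[str, set[str]] = field(default_factory=dict)
    reaction_products: dict[str, set[str]] = field(default_factory=dict)
    #: records (metabolite_id, reaction_id, mode in {activator, inhibitor})
    allosteric: set[tuple[str, str, str]] = field(default_factory=set)
    motif_targets: dict[str, set[str]] = field(default_factory=dict)
    background_genes: set[str] = field(default_factory=set)
    #: signal_id -> set of (target_id, kind in {tf, enzyme})
    kinase_targets: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    tf_mode: dict[str, str] = field(default_factory=dict)
    reaction_pathways: dict[str, set[str]] = field(default_factory=dict)
    pathway_class: dict[str, str] = field(default_factory=dict)
    #: genes encoding transcription factors (layer identity of gene ids)
    tf_genes: set[str] = field(default_factory=set)

    # ---- derived identity sets ------------------------------------------

    def all_reactions(self) -> set[str]:
        out: set[str] = set()
        for rs in self.enzyme_reactions.values():
            out |= rs
        return out

    @property
    def enzyme_gene_ids(self) -> set[str]:
        return set(self.enzyme_reactions)

    @property
    def tf_ids(self) -> set[str]:
        return self.tf_genes | set(self.motif_targets)

    @property
    def signal_ids(self) -> set[str]:
        return set(self.kinase_targets)

    def pathway_reactions(self) -> dict[str, set[str]]:
        """Invert reaction -> pathway membership."""
        out: dict[str, set[str]] = {}
        for rxn, pws in self.reaction_pathways.items():
            for pw in pws:
                out.setdefault(pw, set()).add(rxn)
        return out

    # ---- invariants ------------------------------------------------------

    def validate(self) -> None:
        known = self.all_reactions()
        orphans = sorted(
            {r for _, r, _ in self.allosteric if r not in known}
            | {r for r in self.reaction_substrates if r not in known}
            | {r for r in self.reaction_products if r not in known}
            | {r for r in self.reaction_pathways if r not in known}
        )
        if orphans:
            raise IntegrityError(f"reaction ids not mapped to any enzyme gene: {orphans}")
        for _, _, mode in self.allosteric:
            if mode not in ALLOSTERIC_MODES:
                raise IntegrityError(f"unknown allosteric mode {mode!r}")
        stray = sorted(
            {g for targets in self.motif_targets.values() for g in targets}
            - self.background_genes
        )
        if stray:
            raise IntegrityError(f"motif target genes outside background: {stray[:5]}")
        for tf, mode in self.tf_mode.items():
            if mode not in TF_MODES:
                raise IntegrityError(f"unknown tf mode {mode!r} for {tf}")
        for pw, cls in self.pathway_class.items():
            if cls not in PATHWAY_CLASSES:
                raise IntegrityError(f"unknown pathway class {cls!r} for {pw}")
        overlap = (self.tf_ids & self.enzyme_gene_ids) | (self.tf_ids & self.signal_ids) | (
            self.enzyme_gene_ids & self.signal_ids
        )
        if overlap:
            raise IntegrityError(
                f"layer identity sets (TF/enzyme/signal) must be disjoint: {sorted(overlap)[:5]}"
            )
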