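import numpy as np
import pandas as pd
import pytest

from transomix import PipelineConfig, generate_study_bundle
from transomix.datatypes import OmicsTimeCourse

TIMES = (0, 20, 60, 120, 240)


def make_tc(rows: dict[str, dict], layer: str = "metabolite") -> OmicsTimeCourse:
    """Build a small time course from {molecule: {(genotype, time): [reps]}}.

    Missing (genotype, time) entries and None values become NaN.
    """
    n_rep = max(
        len(v) for per_mol in rows.values() for v in per_mol.values()
    )
    genotypes = sorted({g for per_mol in rows.values() for g, _t in per_mol}, reverse=True)
    times = sorted({t for per_mol in rows.values() for _g, t in per_mol})
    cols = pd.MultiIndex.from_tuples(
        [(g, t, r + 1) for g in genotypes for t in times for r in range(n_rep)],
        names=["genotype", "time", "replicate"],
    )
    data = pd.DataFrame(np.nan, index=pd.Index(rows, name="molecule_id"), columns=cols)
    for mol, per_mol in rows.items():
        for (g, t), reps in per_mol.items():
            for r, val in enumerate(reps):
                if val is not None:
                    data.loc[mol, (g, t, r + 1)] = float(val)
    return OmicsTimeCourse(layer, data)


def flat_tc(mol_means: dict[str, float], layer: str = "metabolite",
            n_rep: int = 5) -> OmicsTimeCourse:
    """Noise-free constant time course at the given per-molecule means."""
    rows = {
        mol: {(g, t): [mean] * n_rep for g in ("WT", "OB") for t in TIMES}
        for mol, mean in mol_means.items()
    }
    return make_tc(rows, layer)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def bundle():
    """One wired synthetic study (time courses, knowledge base, truth)."""
    return generate_study_bundle(seed=1)
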