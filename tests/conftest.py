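import numpy as np
import pandas as pd
import pytest

from decaychase import ChaseExperiment, PercentRemainingCurves


@pytest.fixture
def default_grid():
    return np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])


def make_curves(grid, control, ko, genes=None):
    """Assemble PercentRemainingCurves from per-gene (subjects x time) arrays.

    ``control``/``ko`` map gene -> ndarray of shape (n_subjects, n_time).
    """
    genes = pd.Index(list(control) if genes is None else genes, name="gene_id")
    n_c = next(iter(control.values())).shape[0]
    n_k = next(iter(ko.values())).shape[0]
    data = {
        "control": np.stack([np.asarray(control[g], dtype=float) for g in genes]),
        "ko": np.stack([np.asarray(ko[g], dtype=float) for g in genes]),
    }
    return PercentRemainingCurves(
        genes=genes,
        timepoints=np.asarray(grid, dtype=float),
        subjects={"control": [f"c{i}" for i in range(n_c)], "ko": [f"k{i}" for i in range(n_k)]},
        data=data,
    )


@pytest.fixture
def tiny_experiment():
    """3 genes x 2 genotypes x 2 subjects x 3 timepoints, hand-sized counts."""
    genes = pd.Index(["g1", "g2", "g3"], name="gene_id")
    samples = []
    counts = {}
    rng = np.random.default_rng(0)
    for geno in ("control", "ko"):
        for subj in ("m1", "m2"):
            for t in (0.0, 30.0, 60.0):
                sid = f"{geno}_{subj}_t{t:g}"
                samples.append({"sample_id": sid, "genotype": geno, "subject": subj, "time_min": t})
                counts[sid] = rng.integers(10, 1000, size=3)
    return ChaseExperiment(
        counts=pd.DataFrame(counts, index=genes),
        gene_annotation=pd.DataFrame(
            {"symbol": ["Aaa", "Bbb", "Ccc"], "biotype": ["protein_coding"] * 3, "length_bp": [1000, 500, 2000]},
            index=genes,
        ),
        sample_sheet=pd.DataFrame(samples).set_index("sample_id"),
    )
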