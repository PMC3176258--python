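"""Shared fixtures: small hand-built datasets and cached synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sensisig.dataio import (
    CLASS_CONTROL,
    CLASS_NONSENSITIZER,
    CLASS_SENSITIZER,
    Dataset,
    POTENCY_NONE,
    VEHICLE_DMSO,
    VEHICLE_WATER,
    assemble_dataset,
)
from sensisig.simulate import SynthConfig, generate_dataset

STRONG_EFFECTS = {"extreme": 2.0, "strong": 2.0, "moderate": 2.0, "weak": 2.0}


def toy_dataset(
    X: np.ndarray,
    classes: list[str],
    gene_ids: list[str] | None = None,
    compounds: list[str] | None = None,
    vehicles: list[str] | None = None,
) -> Dataset:
    """Build a Dataset from a genes x samples array and per-sample classes.

    By default each sample is its own compound (replicate 1); sensitizers get
    placeholder potency 'moderate'.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_genes, n_samples = X.shape
    assert len(classes) == n_samples
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    if compounds is None:
        compounds = []
        counts: dict[str, int] = {"s": 0, "n": 0, "c": 0}
        for c in classes:
            if c == CLASS_SENSITIZER:
                counts["s"] += 1
                compounds.append(f"cmp_s{counts['s']}")
            elif c == CLASS_NONSENSITIZER:
                counts["n"] += 1
                compounds.append(f"cmp_n{counts['n']}")
            else:
                compounds.append(VEHICLE_DMSO)
    vehicles = vehicles or ["DMSO"] * n_samples
    sample_ids = [f"smp{i}" for i in range(n_samples)]
    reps: dict[str, int] = {}
    rows = []
    for sid, comp, cls, veh in zip(sample_ids, compounds, classes, vehicles):
        reps[comp] = reps.get(comp, 0) + 1
        rows.append(
            dict(
                sample_id=sid,
                compound_id=comp,
                class_label=cls,
                vehicle=veh,
                replicate=reps[comp],
                potency="moderate" if cls == CLASS_SENSITIZER else POTENCY_NONE,
            )
        )
    expr = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    annot = pd.DataFrame(rows).set_index("sample_id")
    return assemble_dataset(expr, annot)


def two_cluster_dataset(
    n_per_class: int = 10,
    n_genes: int = 5,
    gap: float = 4.0,
    noise: float = 0.3,
    seed: int = 0,
    replicates: int = 1,
) -> Dataset:
    """Well-separated two-class dataset: class means differ by ``gap`` on all genes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0.0, noise, size=(n_genes, n))
    X[:, :n_per_class] += gap
    classes = [CLASS_SENSITIZER] * n_per_class + [CLASS_NONSENSITIZER] * n_per_class
    compounds = None
    if replicates > 1:
        assert n_per_class % replicates == 0
        compounds = []
        for label, tag in ((CLASS_SENSITIZER, "s"), (CLASS_NONSENSITIZER, "n")):
            for i in range(n_per_class):
                compounds.append(f"cmp_{tag}{i // replicates}")
    return toy_dataset(X, classes, compounds=compounds)


@pytest.fixture(scope="session")
def study_strong():
    """Strong-effect study-design dataset reused across expensive tests."""
    cfg = SynthConfig(potency_effects=dict(STRONG_EFFECTS), seed=0)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_recovery():
    """100-gene / 10-informative / 38-compound dataset for recovery checks."""
    cfg = SynthConfig(
        n_genes=100,
        n_informative=10,
        n_sens_compounds=19,
        n_nonsens_compounds=19,
        potency_effects=dict(STRONG_EFFECTS),
        seed=0,
    )
    return generate_dataset(cfg)
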