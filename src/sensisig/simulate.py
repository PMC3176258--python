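"""Synthetic expression data with the structure of a chemical-stimulation study.

The generator emulates a bulk transcriptomics screen in which a DC-like cell
line is stimulated with a panel of sensitizing and non-sensitizing chemicals
(in replicate) plus solvent controls.  All values are on the log2 scale.
The generative model, drawn from a single seeded RNG stream in a fixed,
documented order:

1. per-gene baseline  b_g ~ Normal(baseline_mean, baseline_sd^2);
2. a set of *informative* genes shared by all sensitizers, with loadings
   u_g = sign_g * |Normal(1, 0.25^2)|; each sensitizer compound c of potency
   class pi_c shifts those genes by potency_effects[pi_c] * u_g;
3. every chemical compound (both classes) additionally carries an
   idiosyncratic program: a random fraction of genes shifted by
   Normal(0, idiosyncratic_sd^2) — class separation therefore genuinely
   requires the shared informative axis;
4. vehicle controls are baseline only;
5. each sample adds i.i.d. replicate noise Normal(0, noise_sd^2);
6. compounds named in ``outlier_compounds`` have their whole effect vector
   multiplied by the given factor, emulating the occasional compound whose
   profile dominates the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .dataio import (
    CLASS_CONTROL,
    CLASS_NONSENSITIZER,
    CLASS_SENSITIZER,
    Dataset,
    POTENCY_LEVELS,
    POTENCY_NONE,
    VEHICLE_DMSO,
    VEHICLE_WATER,
    assemble_dataset,
)

# Potency class sizes of a typical 20-sensitizer reference panel
# (4 extreme / 4 strong / 8 moderate / 4 weak).
STUDY_POTENCY_COUNTS = {"extreme": 4, "strong": 4, "moderate": 8, "weak": 4}


@dataclass
class SynthConfig:
    """All generative parameters; defaults reproduce the study layout.

    The default design is 20 sensitizing + 20 non-sensitizing compounds in
    triplicate plus 12 DMSO and 12 water control replicates (144 samples),
    at a desk-scale gene count of 2000.
    """

    n_genes: int = 2000
    n_informative: int = 100
    n_sens_compounds: int = 20
    n_nonsens_compounds: int = 20
    replicates: int = 3
    n_controls_per_vehicle: int = 12
    potency_effects: dict[str, float] = field(
        default_factory=lambda: {"extreme": 2.0, "strong": 1.5, "moderate": 1.0, "weak": 0.6}
    )
    potency_assignment: Literal["round_robin", "study_table"] = "round_robin"
    idiosyncratic_sd: float = 0.4
    idiosyncratic_frac: float = 0.05
    noise_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    outlier_compounds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must be in [0, n_genes]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("idiosyncratic_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.idiosyncratic_frac <= 1:
            raise ValueError("idiosyncratic_frac must be in [0, 1]")
        eff = [self.potency_effects[p] for p in POTENCY_LEVELS]
        if any(np.diff(eff) > 0) or eff[-1] < 0:
            raise ValueError(
                "potency_effects must satisfy extreme >= strong >= moderate >= weak >= 0"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    informative_genes: list[str]
    loadings: pd.Series  # per informative gene
    compound_effects: pd.DataFrame  # compound_id, class_label, potency, multiplier


def default_study_design(**overrides) -> SynthConfig:
    """Configuration reproducing the study's sample layout (144 samples)."""
    return SynthConfig(**overrides)


def _assign_potencies(cfg: SynthConfig) -> list[str]:
    if cfg.potency_assignment == "round_robin":
        return [POTENCY_LEVELS[i % 4] for i in range(cfg.n_sens_compounds)]
    if cfg.potency_assignment == "study_table":
        seq: list[str] = []
        for level in POTENCY_LEVELS:
            seq.extend([level] * STUDY_POTENCY_COUNTS[level])
        if len(seq) < cfg.n_sens_compounds:
            seq.extend(
                POTENCY_LEVELS[i % 4] for i in range(cfg.n_sens_compounds - len(seq))
            )
        return seq[: cfg.n_sens_compounds]
    raise ValueError(f"unknown potency_assignment {cfg.potency_assignment!r}")


def generate_dataset(cfg: SynthConfig) -> tuple[Dataset, SynthTruth]:
    """Draw one dataset from the generative model; fully determined by cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    # (1) baselines
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    # (2) shared sensitizer axis on a random informative subset
    informative_idx = np.sort(
        rng.choice(cfg.n_genes, size=cfg.n_informative, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    loadings = signs * np.abs(rng.normal(1.0, 0.25, size=cfg.n_informative))

    potencies = _assign_potencies(cfg)
    compounds: list[tuple[str, str, str]] = []  # (compound_id, class_label, potency)
    for i in range(cfg.n_sens_compounds):
        compounds.append((f"sens_{i + 1:02d}", CLASS_SENSITIZER, potencies[i]))
    for i in range(cfg.n_nonsens_compounds):
        compounds.append((f"nonsens_{i + 1:02d}", CLASS_NONSENSITIZER, POTENCY_NONE))

    # (2)+(3) per-compound effect vectors, in compound order
    effect = {}
    records = []
    for cid, label, pot in compounds:
        vec = np.zeros(cfg.n_genes)
        if label == CLASS_SENSITIZER:
            vec[informative_idx] += cfg.potency_effects[pot] * loadings
        n_idio = int(round(cfg.idiosyncratic_frac * cfg.n_genes))
        if n_idio > 0 and cfg.idiosyncratic_sd > 0:
            idio_idx = rng.choice(cfg.n_genes, size=n_idio, replace=False)
            vec[idio_idx] += rng.normal(0.0, cfg.idiosyncratic_sd, size=n_idio)
        mult = cfg.outlier_compounds.get(cid, 1.0)
        effect[cid] = mult * vec
        records.append(
            {"compound_id": cid, "class_label": label, "potency": pot, "multiplier": mult}
        )
    unknown_outliers = set(cfg.outlier_compounds) - set(effect)
    if unknown_outliers:
        raise ValueError(f"outlier_compounds name unknown compounds: {sorted(unknown_outliers)}")

    # (4)-(5) assemble samples: chemicals in compound order, then controls
    sample_ids: list[str] = []
    annot_rows: list[dict] = []
    columns: list[np.ndarray] = []
    vehicles = [VEHICLE_DMSO, VEHICLE_WATER]
    for k, (cid, label, pot) in enumerate(compounds):
        vehicle = "DMSO" if vehicles[k % 2] == VEHICLE_DMSO else "water"
        for r in range(1, cfg.replicates + 1):
            sid = f"{cid}_r{r}"
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            columns.append(baseline + effect[cid] + noise)
            sample_ids.append(sid)
            annot_rows.append(
                dict(sample_id=sid, compound_id=cid, class_label=label,
                     vehicle=vehicle, replicate=r, potency=pot)
            )
    for token, vehicle in ((VEHICLE_DMSO, "DMSO"), (VEHICLE_WATER, "water")):
        for r in range(1, cfg.n_controls_per_vehicle + 1):
            sid = f"{token}_r{r}"
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            columns.append(baseline + noise)
            sample_ids.append(sid)
            annot_rows.append(
                dict(sample_id=sid, compound_id=token, class_label=CLASS_CONTROL,
                     vehicle=vehicle, replicate=r, potency=POTENCY_NONE)
            )

    expr = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((cfg.n_genes, 0)),
        index=genes,
        columns=sample_ids,
    )
    annot = pd.DataFrame(annot_rows).set_index("sample_id")
    ds = assemble_dataset(expr, annot)
    truth = SynthTruth(
        informative_genes=[genes[i] for i in informative_idx],
        loadings=pd.Series(loadings, index=[genes[i] for i in informative_idx]),
        compound_effects=pd.DataFrame(records),
    )
    return ds, truth


def write_truth(truth: SynthTruth, path) -> None:
    """Write ground truth as TSV (gene_id, is_informative flag, loading)."""
    df = pd.DataFrame(
        {
            "gene_id": truth.informative_genes,
            "is_informative": 1,
            "loading": truth.loadings.values,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
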