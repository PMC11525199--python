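"""Synthetic lineage-tracing cohorts and donor mutation tables.

Both generators embed their ground truth in a JSON sidecar so downstream
fits can be checked for parameter recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .mutation_landscape import (
    PATH_GOF,
    UNKN_NE,
    Donor,
    MutantClone,
    load_annotation_snapshot,
)
from .progenitor_model import CloneRecord, ModelParams, simulate_clones_batch

__all__ = ["TracingDesign", "DonorDesign", "gen_tracing_dataset", "gen_donor_dataset"]


@dataclass
class TracingDesign:
    """Design of a simulated lineage-tracing experiment."""

    n_mice: int
    clones_per_mouse: float
    timepoints: list[float]  # days
    params_by_condition: dict[str, ModelParams]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_mice <= 0 or self.clones_per_mouse <= 0:
            raise ValueError("n_mice and clones_per_mouse must be > 0")
        if not self.timepoints:
            raise ValueError("at least one timepoint required")
        if not self.params_by_condition:
            raise ValueError("at least one condition required")


@dataclass
class DonorDesign:
    """Design of a simulated human donor cohort.

    Clone counts per donor and effect class are Poisson with mean
    ``area_cm2 * (intercept + slope * age)``; the Path/GoF rate is
    weight-class specific, the Unkn/NE rate shared.  VAFs come from a
    right-skewed Beta distribution truncated below at the detection floor.
    """

    n_donors: int  # per weight class
    age_range: tuple[float, float] = (35.0, 80.0)
    sample_area_mm2: float = 2.0
    samples_per_donor: int = 700
    pathgof_rate: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"non-OW": (0.05, 0.022), "OW-OB": (0.05, 0.098)})
    unknne_rate: tuple[float, float] = (0.05, 0.010)
    vaf_shape: tuple[float, float] = (1.0, 40.0)
    detection_floor: float = 0.01
    h1047r_share: float = 0.19
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_donors <= 0:
            raise ValueError("n_donors must be > 0")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be > 0")
        for label, (a, b) in {**self.pathgof_rate, "Unkn/NE": self.unknne_rate}.items():
            for age in self.age_range:
                if a + b * age < 0:
                    raise ValueError(
                        f"rate for {label} is negative at age {age}: {a + b * age}")


def gen_tracing_dataset(design: TracingDesign, out_path: str | Path | None = None
                        ) -> pd.DataFrame:
    """Simulate per-mouse clone cohorts for every condition and timepoint.

    One group of ``n_mice`` mice is simulated per (condition, timepoint);
    each mouse contributes a Poisson number of clones, each the progeny of a
    single founder progenitor.  Returns the clone table; when ``out_path``
    is given, writes it as TSV with a ``<stem>.truth.json`` sidecar.
    """
    root = np.random.SeedSequence(design.seed)
    rows = []
    conditions = sorted(design.params_by_condition)
    streams = root.spawn(len(conditions) * len(design.timepoints) * design.n_mice)
    k = 0
    for cond in conditions:
        params = design.params_by_condition[cond]
        for t in design.timepoints:
            for mouse in range(design.n_mice):
                ss = streams[k]
                k += 1
                rng = np.random.default_rng(ss)
                n_clones = int(rng.poisson(design.clones_per_mouse))
                if n_clones == 0:
                    continue
                states = simulate_clones_batch(params, t, n_clones, seed=ss.spawn(1)[0])
                animal = f"{cond}_t{int(t)}_m{mouse + 1}"
                for p, d, s in states:
                    rows.append({"animal_id": animal, "condition": cond,
                                 "t_days": float(t), "basal": int(p + d),
                                 "suprabasal": int(s)})
    table = pd.DataFrame(rows, columns=["animal_id", "condition", "t_days",
                                        "basal", "suprabasal"])
    if out_path is not None:
        out_path = Path(out_path)
        table.to_csv(out_path, sep="\t", index=False)
        truth = {
            "seed": design.seed,
            "n_mice": design.n_mice,
            "clones_per_mouse": design.clones_per_mouse,
            "timepoints": list(design.timepoints),
            "params_by_condition": {c: p.to_dict()
                                    for c, p in design.params_by_condition.items()},
        }
        out_path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))
    return table


def records_from_frame(table: pd.DataFrame) -> list[CloneRecord]:
    """Clone table rows as typed records."""
    return [CloneRecord(animal_id=str(r.animal_id), condition=str(r.condition),
                        t_days=float(r.t_days), m=int(r.basal), n=int(r.suprabasal))
            for r in table.itertuples()]


def _truncated_beta(rng: np.random.Generator, shape: tuple[float, float],
                    floor: float, size: int) -> np.ndarray:
    a, b = shape
    lo = beta_dist.cdf(floor, a, b)
    u = rng.uniform(lo, 1.0, size=size)
    return np.clip(beta_dist.ppf(u, a, b), floor, 1.0)


_UNKN_POOL = ["A66T", "L113F", "P124L", "R274K", "S326F", "T462I", "D538N",
              "V636I", "R693Q", "T783M", "D830N", "V955I", "R975S", "L1006F"]


def gen_donor_dataset(design: DonorDesign,
                      out_prefix: str | Path | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a donor table and per-sample mutant-clone table.

    Donor ages are uniform on ``age_range``; BMI is drawn within the donor's
    designed weight class.  Returns ``(mutations, donors, truth)``; when
    ``out_prefix`` is given, writes ``<prefix>.mutations.tsv``,
    ``<prefix>.donors.tsv`` and ``<prefix>.truth.json``.
    """
    rng = np.random.default_rng(design.seed)
    annotation = load_annotation_snapshot()
    pathogenic = sorted(a for (g, a) in annotation if g == "PIK3CA")
    other_path = [a for a in pathogenic if a != "H1047R"]

    donor_rows, clone_rows = [], []
    area_cm2 = design.samples_per_donor * design.sample_area_mm2 / 100.0
    counter = 0
    for wclass in ("non-OW", "OW-OB"):
        for i in range(design.n_donors):
            donor_id = f"{wclass.replace('-', '')}_{i + 1:02d}"
            age = float(rng.uniform(*design.age_range))
            bmi = float(rng.uniform(18.5, 24.9) if wclass == "non-OW"
                        else rng.uniform(25.1, 38.0))
            donor_rows.append({"donor_id": donor_id, "age": age, "bmi": bmi,
                               "n_samples": design.samples_per_donor,
                               "sample_area_mm2": design.sample_area_mm2})
            for cls, (a, b) in (("Path/GoF", design.pathgof_rate[wclass]),
                                ("Unkn/NE", design.unknne_rate)):
                mean = area_cm2 * (a + b * age)
                n_clones = int(rng.poisson(mean))
                if n_clones == 0:
                    continue
                vafs = _truncated_beta(rng, design.vaf_shape,
                                       design.detection_floor, n_clones)
                for v in vafs:
                    counter += 1
                    if cls == "Path/GoF":
                        if rng.random() < design.h1047r_share or not other_path:
                            aa = "H1047R"
                        else:
                            aa = other_path[rng.integers(len(other_path))]
                    else:
                        aa = _UNKN_POOL[rng.integers(len(_UNKN_POOL))]
                    sample = f"{donor_id}_s{rng.integers(1, design.samples_per_donor + 1):04d}"
                    clone_rows.append({"donor_id": donor_id, "sample_id": sample,
                                       "gene": "PIK3CA", "aa_change": aa,
                                       "consequence": "missense",
                                       "vaf": float(v)})
    donors = pd.DataFrame(donor_rows)
    mutations = pd.DataFrame(clone_rows, columns=["donor_id", "sample_id", "gene",
                                                  "aa_change", "consequence", "vaf"])
    truth = {
        "seed": design.seed,
        "pathgof_rate": {k: list(v) for k, v in design.pathgof_rate.items()},
        "unknne_rate": list(design.unknne_rate),
        "area_cm2_per_donor": area_cm2,
        "vaf_shape": list(design.vaf_shape),
        "detection_floor": design.detection_floor,
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        mutations.to_csv(out_prefix.with_suffix(".mutations.tsv"), sep="\t", index=False)
        donors.to_csv(out_prefix.with_suffix(".donors.tsv"), sep="\t", index=False)
        out_prefix.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))
    return mutations, donors, truth


def donors_from_frame(table: pd.DataFrame) -> list[Donor]:
    return [Donor(donor_id=str(r.donor_id), age=float(r.age), bmi=float(r.bmi),
                  n_samples=int(r.n_samples),
                  sample_area_mm2=float(getattr(r, "sample_area_mm2", 2.0)))
            for r in table.itertuples()]


def clones_from_frame(table: pd.DataFrame,
                      annotation_map: dict | None = None) -> list[MutantClone]:
    if annotation_map is None:
        annotation_map = load_annotation_snapshot()
    from .mutation_landscape import classify_effect
    out = []
    for r in table.itertuples():
        cls = classify_effect(str(r.aa_change), str(r.gene), annotation_map,
                              str(r.consequence))
        out.append(MutantClone(donor_id=str(r.donor_id), sample_id=str(r.sample_id),
                               gene=str(r.gene), aa_change=str(r.aa_change),
                               vaf=float(r.vaf), consequence=str(r.consequence),
                               effect_class=cls))
    return out
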