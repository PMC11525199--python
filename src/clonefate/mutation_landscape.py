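"""Human mutant-clone analysis for targeted deep sequencing of normal tissue.

Classifies missense clones as pathogenic/gain-of-function (Path/GoF) against
a packaged annotation snapshot, computes per-donor clone densities, summed
VAF and tissue coverage, fits the age x weight-class x pathogenicity linear
model with an ANOVA table, Tukey post-hoc contrasts and per-group
accumulation rates, and lays out patchwork plots of clones as circles.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import t as t_dist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stat_tests import binomial_two_tailed

__all__ = [
    "MutantClone",
    "Donor",
    "DensityModelResult",
    "SummedVaf",
    "PATH_GOF",
    "UNKN_NE",
    "NOT_APPLICABLE",
    "BMI_CUTOFF",
    "load_annotation_snapshot",
    "classify_effect",
    "weight_class",
    "total_area",
    "clone_density",
    "summed_vaf",
    "tissue_coverage",
    "density_model",
    "patchwork_layout",
    "pathgof_enrichment",
]

logger = logging.getLogger(__name__)

PATH_GOF = "Path/GoF"
UNKN_NE = "Unkn/NE"
NOT_APPLICABLE = "n.a."

#: BMI threshold splitting non-overweight from overweight-obese donors
BMI_CUTOFF = 25.0

_AA_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


@dataclass(frozen=True)
class MutantClone:
    donor_id: str
    sample_id: str
    gene: str
    aa_change: str
    vaf: float
    consequence: str = "missense"
    effect_class: str = NOT_APPLICABLE

    def __post_init__(self) -> None:
        if not (0 < self.vaf <= 1):
            raise ValueError(f"vaf must be in (0, 1], got {self.vaf}")


@dataclass(frozen=True)
class Donor:
    donor_id: str
    age: float
    bmi: float
    n_samples: int
    sample_area_mm2: float = 2.0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0, got {self.n_samples}")
        if self.sample_area_mm2 <= 0:
            raise ValueError(f"sample_area_mm2 must be > 0, got {self.sample_area_mm2}")

    @property
    def weight_class(self) -> str:
        return weight_class(self.bmi)

    @property
    def area_cm2(self) -> float:
        return total_area(self.n_samples, self.sample_area_mm2)


@dataclass
class SummedVaf:
    total: float
    per_cm2: float


@dataclass
class DensityModelResult:
    coefficients: pd.DataFrame  # term, estimate, se
    anova: pd.DataFrame  # term, F, df, p
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    rates: pd.DataFrame  # group, slope_per_cm2_yr, rate_per_dm2_yr, ci_low, ci_high
    model: object = field(repr=False, default=None)


def weight_class(bmi: float) -> str:
    """Dichotomize BMI at 25 kg/m2 into non-OW vs OW-OB."""
    return "OW-OB" if bmi >= BMI_CUTOFF else "non-OW"


def load_annotation_snapshot() -> dict[tuple[str, str], str]:
    """Packaged pathogenic/GoF variant snapshot as a (gene, aa_change) map."""
    ref = importlib.resources.files("clonefate.data") / "pik3ca_pathogenic.tsv"
    table = pd.read_csv(ref, sep="\t")
    return {(g, a): c for g, a, c in zip(table["gene"], table["aa_change"], table["class"])}


def classify_effect(aa_change: str, gene: str = "PIK3CA",
                    annotation_map: dict | None = None,
                    consequence: str = "missense") -> str:
    """Effect class of one variant: Path/GoF, Unkn/NE or n.a.

    Missense variants present in the annotation snapshot are Path/GoF, other
    missense variants default to Unkn/NE; synonymous and other consequences
    are not applicable.  Unparseable protein notation raises ``ValueError``
    (callers flag and exclude the record).
    """
    if consequence != "missense":
        return NOT_APPLICABLE
    if not _AA_RE.match(aa_change):
        raise ValueError(f"unparseable amino-acid change {aa_change!r}")
    if annotation_map is None:
        annotation_map = load_annotation_snapshot()
    return PATH_GOF if (gene, aa_change) in annotation_map else UNKN_NE


def classify_clones(clones: Iterable[MutantClone],
                    annotation_map: dict | None = None) -> list[MutantClone]:
    """Re-derive effect classes for a clone table, dropping unparseable rows."""
    if annotation_map is None:
        annotation_map = load_annotation_snapshot()
    out = []
    for c in clones:
        try:
            cls = classify_effect(c.aa_change, c.gene, annotation_map, c.consequence)
        except ValueError:
            logger.warning("excluding clone with unparseable aa change %r (donor %s)",
                           c.aa_change, c.donor_id)
            continue
        out.append(MutantClone(c.donor_id, c.sample_id, c.gene, c.aa_change,
                               c.vaf, c.consequence, cls))
    return out


def total_area(n_samples: int, sample_area_mm2: float = 2.0) -> float:
    """Total sequenced epithelium area in cm2 from a gridded sample array."""
    if n_samples < 0:
        raise ValueError(f"n_samples must be >= 0, got {n_samples}")
    return n_samples * sample_area_mm2 / 100.0


def _matching(donor: Donor, clones: Iterable[MutantClone],
              effect_class: str | None) -> list[MutantClone]:
    return [c for c in clones
            if c.donor_id == donor.donor_id
            and c.consequence == "missense"
            and (effect_class is None or c.effect_class == effect_class)]


def clone_density(donor: Donor, clones: Iterable[MutantClone],
                  effect_class: str | None = None) -> float:
    """Missense clones per cm2 of sequenced epithelium for one donor."""
    area = donor.area_cm2
    if area <= 0:
        raise ValueError(f"donor {donor.donor_id} has zero sequenced area")
    return len(_matching(donor, clones, effect_class)) / area


def summed_vaf(donor: Donor, clones: Iterable[MutantClone],
               effect_class: str | None = None) -> SummedVaf:
    """Summed VAF of matching clones, both raw and per cm2."""
    s = sum(c.vaf for c in _matching(donor, clones, effect_class))
    return SummedVaf(total=s, per_cm2=s / donor.area_cm2)


def tissue_coverage(clones: Iterable[MutantClone], donor: Donor,
                    sample_area_mm2: float | None = None,
                    ploidy_factor: float = 2.0,
                    effect_class: str | None = None) -> float:
    """Fraction of the donor's sequenced tissue covered by matching clones.

    Each heterozygous diploid clone covers ``min(1, ploidy_factor * vaf)`` of
    its sample; coverage is the clone-area sum over the donor's total area,
    capped at 1.
    """
    if sample_area_mm2 is None:
        sample_area_mm2 = donor.sample_area_mm2
    area_mm2 = donor.area_cm2 * 100.0
    covered = sum(min(1.0, ploidy_factor * c.vaf) * sample_area_mm2
                  for c in _matching(donor, clones, effect_class))
    return min(1.0, covered / area_mm2)


def density_table(donors: Sequence[Donor], clones: Iterable[MutantClone],
                  response: str = "density") -> pd.DataFrame:
    """Donor-level modeling table: two rows per donor, one per effect class."""
    clones = list(clones)
    rows = []
    for d in donors:
        for cls in (PATH_GOF, UNKN_NE):
            if response == "density":
                y = clone_density(d, clones, cls)
            elif response == "summed_vaf":
                y = summed_vaf(d, clones, cls).per_cm2
            else:
                raise ValueError(f"unknown response {response!r}")
            rows.append({"donor_id": d.donor_id, "age": d.age,
                         "weight": d.weight_class, "path": cls, "y": y})
    return pd.DataFrame(rows)


def density_model(donors: Sequence[Donor], clones: Iterable[MutantClone],
                  response: str = "density", ss_type: int = 1) -> DensityModelResult:
    """Age x weight-class x pathogenicity linear model of clone density.

    Ordinary least squares on donor-level rows (one per donor and effect
    class) with all interactions; the ANOVA F table uses sequential (type I)
    sums of squares in entry order age, weight, pathogenicity by default
    (``ss_type=2`` switches to type II).  Tukey-adjusted pairwise contrasts
    compare the four weight x pathogenicity groups, and per-group age slopes
    are re-expressed as clones per dm2 per year (x100) with 95% CIs from the
    coefficient covariance.
    """
    donors = list(donors)
    by_class: dict[str, int] = {}
    for d in donors:
        by_class[d.weight_class] = by_class.get(d.weight_class, 0) + 1
    if any(by_class.get(w, 0) < 2 for w in ("non-OW", "OW-OB")):
        raise ValueError(f"need >= 2 donors per weight class, got {by_class}")
    df = density_table(donors, clones, response=response)
    model = smf.ols("y ~ age * C(weight) * C(path)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design: age x weight x pathogenicity "
                         "terms are collinear")
    anova = sm.stats.anova_lm(model, typ=ss_type).reset_index()
    anova = anova.rename(columns={"index": "term", "PR(>F)": "p", "df": "df", "F": "F"})

    coeffs = pd.DataFrame({"term": model.params.index,
                           "estimate": model.params.values,
                           "se": model.bse.values})

    groups = df["weight"] + " / " + df["path"]
    tk = pairwise_tukeyhsd(endog=df["y"].values, groups=groups.values)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    # per-group age slopes: finite difference of the design row in age.
    # Clone counts are Poisson-like, so group variances scale with group
    # means; HC3 robust covariance keeps the slope CIs near nominal
    # coverage under that heteroscedasticity.
    cov = np.asarray(model.get_robustcov_results(cov_type="HC3").cov_params())
    beta = model.params.values
    dof = int(model.df_resid)
    design_info = model.model.data.design_info
    from patsy import dmatrix
    rate_rows = []
    for w in ("non-OW", "OW-OB"):
        for cls in (PATH_GOF, UNKN_NE):
            row0 = np.asarray(dmatrix(design_info, {"age": [0.0], "weight": [w],
                                                    "path": [cls]}))[0]
            row1 = np.asarray(dmatrix(design_info, {"age": [1.0], "weight": [w],
                                                    "path": [cls]}))[0]
            c = row1 - row0
            slope = float(c @ beta)
            # noiseless designs can give a tiny negative quadratic form
            se = math.sqrt(max(0.0, float(c @ cov @ c)))
            tq = t_dist.ppf(0.975, dof)
            rate_rows.append({
                "group": f"{w} / {cls}",
                "slope_per_cm2_yr": slope,
                "rate_per_dm2_yr": 100.0 * slope,
                "ci_low_per_dm2_yr": 100.0 * (slope - tq * se),
                "ci_high_per_dm2_yr": 100.0 * (slope + tq * se),
            })
    rates = pd.DataFrame(rate_rows)
    return DensityModelResult(coefficients=coeffs, anova=anova, tukey=tukey,
                              rates=rates, model=model)


def patchwork_layout(clones: Sequence[MutantClone], sample_ids: Sequence[str],
                     target_area_cm2: float, sample_area_mm2: float = 2.0,
                     ploidy_factor: float = 2.0,
                     seed: int | None = None) -> list[tuple[float, float, float]]:
    """Random patchwork of clones as circles in a square of the target area.

    Whole biopsies (sample ids) are subsampled at random until the target
    area is reached; every clone in a selected biopsy becomes a circle of
    area ``ploidy_factor * vaf * sample_area`` placed uniformly at random.
    Coordinates and radii are in cm; output is seed-reproducible.
    """
    available_cm2 = len(sample_ids) * sample_area_mm2 / 100.0
    if target_area_cm2 > available_cm2 + 1e-12:
        raise ValueError(f"target area {target_area_cm2} cm2 exceeds sampled "
                         f"area {available_cm2} cm2")
    rng = np.random.default_rng(seed)
    order = list(sample_ids)
    rng.shuffle(order)
    chosen: set[str] = set()
    acc = 0.0
    for sid in order:
        if acc >= target_area_cm2:
            break
        chosen.add(sid)
        acc += sample_area_mm2 / 100.0
    side = math.sqrt(target_area_cm2)
    layout = []
    for c in clones:
        if c.sample_id not in chosen:
            continue
        area_cm2 = min(1.0, ploidy_factor * c.vaf) * sample_area_mm2 / 100.0
        radius = math.sqrt(area_cm2 / math.pi)
        x, y = rng.uniform(0.0, side, size=2)
        layout.append((float(x), float(y), float(radius)))
    return layout


def pathgof_enrichment(k_pathgof: int, n_missense: int,
                       p_neutral: float = 0.02) -> dict:
    """Two-tailed binomial enrichment of Path/GoF among missense clones."""
    p = binomial_two_tailed(k_pathgof, n_missense, p_neutral)
    return {"p_value": p, "observed_fraction": k_pathgof / n_missense,
            "observed_percent": round(100.0 * k_pathgof / n_missense)}
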