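"""Synthetic natality cohorts with the joint structure the model assumes.

A cohort is generated in the model's own causal direction: each race group
has a fixed number of births, a birth falls into one birthweight x gestation
stratum by a multinomial draw over race-specific incidence probabilities, and
each birth in a stratum dies before one year with that stratum's mortality
probability.  Two macrosomia strata (MAC with extremely/very preterm
delivery) are structural zeros: such births do not occur.

The default population mirrors the magnitudes seen in recent U.S. national
singleton-birth data: a Black share near 10% of births, an extremely-low-
birthweight/extremely-preterm incidence ratio near 2.75 between race groups,
stratum mortality spanning roughly 0.002 (normal birthweight, term) to 0.41
(ELBW/EPTD), and at least three quarters of each race's births in the
joint-normal reference stratum.

The spec's implied marginal rates, total effect, relative risk, and
percentage attributable under any control strategy are available in closed
form (mixture arithmetic over strata), giving parameter-recovery experiments
an exact ground truth that never touches the inference code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .categorize import (
    BirthRecord,
    BWCategory,
    LGCategory,
    Race,
    StrataCounts,
)
from .mediation import ControlStrategy, run_model1, run_model2
from .posterior import BETA_1_10, PriorSpec

__all__ = [
    "PopulationSpec",
    "SyntheticCohort",
    "default_spec",
    "generate_counts",
    "generate_records",
    "true_marginal_po",
    "true_total_effect",
    "true_relative_risk",
    "true_percent_attributable",
    "recovery_experiment",
]

#: Strata that never occur: macrosomic extremely/very preterm births.
STRUCTURAL_ZEROS = ((BWCategory.MAC - 1, LGCategory.EPTD - 1),
                    (BWCategory.MAC - 1, LGCategory.VPTD - 1))

# gram / completed-week sampling windows per category (inclusive)
_BW_BOUNDS = {1: (250, 999), 2: (1000, 1499), 3: (1500, 2499),
              4: (2500, 4000), 5: (4001, 5500)}
_LG_BOUNDS = {1: (20, 27), 2: (28, 31), 3: (32, 36), 4: (37, 41), 5: (42, 45)}
_LG_INDEX = {"EPTD": 0, "VPTD": 1, "PTD": 2, "TD": 3, "PostTD": 4}


@dataclass(frozen=True)
class PopulationSpec:
    """Generative ground truth for a synthetic cohort.

    ``incidence[race, bw, lg]`` rows sum to one per race; ``mortality`` is
    the per-stratum death probability, zero where the stratum cannot occur.
    Race axis 0 is non-Black, 1 is Black.
    """

    births_per_race: tuple[int, int]
    incidence: np.ndarray
    mortality: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=float)
        mort = np.asarray(self.mortality, dtype=float)
        object.__setattr__(self, "incidence", inc)
        object.__setattr__(self, "mortality", mort)
        if inc.shape != mort.shape or inc.ndim != 3 or inc.shape[0] != 2:
            raise ValueError("incidence and mortality must both be (2, K, K)")
        if (inc < 0).any() or (mort < 0).any() or (mort > 1).any():
            raise ValueError("probabilities out of range")
        sums = inc.sum(axis=(1, 2))
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"incidence rows must sum to 1 per race, got {sums}")
        if any(b <= 0 for b in self.births_per_race):
            raise ValueError("births_per_race must be positive")

    @property
    def k(self) -> int:
        return self.incidence.shape[1]

    def with_seed(self, seed: int) -> "PopulationSpec":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    """A generated cohort: stratum counts, optional records, and the truth."""

    counts: StrataCounts
    spec: PopulationSpec
    records: Optional[list[BirthRecord]] = None


# Default stratum mortality probabilities (non-Black, Black), spanning the
# ~100-fold range between the joint-normal and ELBW/EPTD strata.
_MORT_NON_BLACK = np.array([
    # EPTD   VPTD   PTD    TD     PostTD
    [0.417, 0.094, 0.201, 0.069, 0.076],   # ELBW
    [0.098, 0.043, 0.058, 0.088, 0.044],   # VLBW
    [0.223, 0.039, 0.014, 0.012, 0.034],   # LBW
    [0.050, 0.047, 0.006, 0.002, 0.001],   # NBW
    [0.0,   0.0,   0.013, 0.001, 0.001],   # MAC
])
_MORT_BLACK = np.array([
    [0.410, 0.084, 0.175, 0.059, 0.043],
    [0.083, 0.037, 0.041, 0.084, 0.028],
    [0.161, 0.038, 0.014, 0.011, 0.042],
    [0.032, 0.029, 0.007, 0.003, 0.002],
    [0.0,   0.0,   0.015, 0.002, 0.002],
])

# Non-Black stratum incidence away from the reference cell, and the Black /
# non-Black incidence ratio per stratum; the reference cell absorbs the
# remaining mass per race.
_INC_NON_BLACK = np.array([
    [3.8375e-3, 6.0e-4, 2.0e-4, 1.3e-5, 1.1e-6],
    [8.0e-4, 4.0e-3, 2.5e-3, 4.0e-4, 4.9e-6],
    [2.0e-4, 3.0e-3, 2.8175e-2, 2.2e-2, 6.0e-4],
    [2.1e-5, 4.0e-4, 3.5e-2, np.nan, 3.0e-2],   # NaN = reference remainder
    [0.0,    0.0,    8.0e-4, 8.0e-2, 1.0e-2],
])
_INC_RATIO = np.array([
    [2.75, 2.44, 1.95, 1.61, 2.41],
    [1.88, 2.21, 2.06, 1.68, 1.15],
    [1.91, 1.48, 1.65, 1.78, 1.71],
    [1.45, 1.27, 1.04, np.nan, 0.96],
    [1.0,  1.0,  0.83, 0.57, 0.59],
])


def default_spec(scale: int = 1_000_000, black_share: float = 0.10,
                 seed: int = 0) -> PopulationSpec:
    """Build the default population at ``scale`` total births.

    Non-reference incidence is specified for the non-Black group with the
    Black group's obtained by stratum-specific incidence ratios; the
    joint-normal reference stratum takes the remaining mass in each race
    (>= 0.75 by construction).
    """
    if scale < 10_000:
        raise ValueError("scale must be at least 10,000 births")
    ref = (BWCategory.NBW - 1, LGCategory.TD - 1)
    inc_nb = _INC_NON_BLACK.copy()
    inc_b = inc_nb * _INC_RATIO
    for inc in (inc_nb, inc_b):
        inc[ref] = 0.0
        inc[ref] = 1.0 - inc.sum()
    incidence = np.stack([inc_nb, inc_b])
    mortality = np.stack([_MORT_NON_BLACK, _MORT_BLACK])
    n_black = int(round(scale * black_share))
    return PopulationSpec(
        births_per_race=(scale - n_black, n_black),
        incidence=incidence,
        mortality=mortality,
        seed=seed,
    )


def generate_counts(spec: PopulationSpec) -> SyntheticCohort:
    """Draw stratum births (multinomial) and deaths (binomial) per race."""
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    births = np.zeros((2, k, k), dtype=np.int64)
    deaths = np.zeros((2, k, k), dtype=np.int64)
    for axis in range(2):
        cells = rng.multinomial(spec.births_per_race[axis],
                                spec.incidence[axis].ravel()).reshape(k, k)
        births[axis] = cells
        deaths[axis] = rng.binomial(cells, spec.mortality[axis])
    counts = StrataCounts(births, deaths, scheme="five_by_five")
    return SyntheticCohort(counts=counts, spec=spec)


def generate_records(
    spec: PopulationSpec, missingness: float = 0.0
) -> SyntheticCohort:
    """Generate individual birth records whose aggregation is the cohort.

    Grams and weeks are sampled uniformly within each stratum's category
    window, so classifying and aggregating the records reproduces the
    stratum counts exactly (when no missingness is injected).  With
    ``missingness`` > 0, each record's birthweight or gestation is
    independently blanked with that probability (half-and-half between the
    two fields); ``counts`` still reflects the complete records.
    """
    if not 0.0 <= missingness < 1.0:
        raise ValueError("missingness must be in [0, 1)")
    cohort = generate_counts(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    records: list[BirthRecord] = []
    k = spec.k
    for race in Race:
        for i in range(k):
            for j in range(k):
                n = int(cohort.counts.births[race.axis, i, j])
                if n == 0:
                    continue
                r = int(cohort.counts.deaths[race.axis, i, j])
                g = rng.integers(_BW_BOUNDS[i + 1][0], _BW_BOUNDS[i + 1][1] + 1, n)
                w = rng.integers(_LG_BOUNDS[j + 1][0], _LG_BOUNDS[j + 1][1] + 1, n)
                died = np.zeros(n, dtype=bool)
                died[:r] = True
                rng.shuffle(died)
                for t in range(n):
                    records.append(BirthRecord(race, int(g[t]), int(w[t]), bool(died[t])))
    if missingness > 0:
        miss = rng.random(len(records)) < missingness
        which_bw = rng.random(len(records)) < 0.5
        for t in np.flatnonzero(miss):
            rec = records[t]
            if which_bw[t]:
                records[t] = BirthRecord(rec.race, None, rec.gestation_wk, rec.infant_death)
            else:
                records[t] = BirthRecord(rec.race, rec.birthweight_g, None, rec.infant_death)
    cohort.records = records
    return cohort


# ---------------------------------------------------------------------------
# analytic ground truth (pure mixture arithmetic; no inference code involved)


def true_marginal_po(spec: PopulationSpec) -> np.ndarray:
    """Exact marginal mortality rate per race: sum of incidence * mortality."""
    return (spec.incidence * spec.mortality).sum(axis=(1, 2))


def true_total_effect(spec: PopulationSpec) -> float:
    m = true_marginal_po(spec)
    return float(m[Race.BLACK.axis] - m[Race.NON_BLACK.axis])


def true_relative_risk(spec: PopulationSpec) -> float:
    m = true_marginal_po(spec)
    return float(m[Race.BLACK.axis] / m[Race.NON_BLACK.axis])


def true_percent_attributable(
    spec: PopulationSpec, strategy: ControlStrategy
) -> float:
    """Exact PA: targeted strata take their reference stratum's mortality."""
    te = true_total_effect(spec)
    mort = spec.mortality.copy()
    for cell in strategy.targeted_cells():
        ref = strategy.reference_for(cell)
        for axis in range(2):
            mort[axis][cell] = spec.mortality[axis][ref]
    new_marginal = (spec.incidence * mort).sum(axis=(1, 2))
    cde_true = new_marginal[Race.BLACK.axis] - new_marginal[Race.NON_BLACK.axis]
    return float(100.0 * (te - cde_true) / te)


def dominant_abnormal_cell(spec: PopulationSpec) -> tuple[int, int]:
    """Non-reference stratum with the largest true single-cell PA."""
    ref = (BWCategory.NBW - 1, LGCategory.TD - 1)
    best, best_pa = None, -np.inf
    for i in range(spec.k):
        for j in range(spec.k):
            if (i, j) == ref or spec.incidence[:, i, j].sum() == 0:
                continue
            pa = true_percent_attributable(
                spec, ControlStrategy("five_by_five", (i, j)))
            if pa > best_pa:
                best, best_pa = (i, j), pa
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# parameter recovery


def recovery_experiment(
    spec: PopulationSpec,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = 4_000,
    seeds: Sequence[int] = tuple(range(20)),
    min_cell_births: int = 1_000,
) -> pd.DataFrame:
    """Replicate cohorts and check CrI coverage of the analytic truths.

    For each replicate seed the cohort is regenerated, the per-stratum and
    binary analyses are run, and we record whether each well-populated
    stratum's true mortality, the true total effect, and the true PA of the
    spec's dominant abnormal stratum (and of the joint binary control) fall
    inside their reported 95% credibility intervals.  Returns one row per
    replicate; column means estimate coverage.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two replicate seeds")
    te_true = true_total_effect(spec)
    dom = dominant_abnormal_cell(spec)
    pa_true = true_percent_attributable(
        spec, ControlStrategy("five_by_five", dom))
    pa_true_binary = true_percent_attributable(
        spec, ControlStrategy("five_by_five", "all_abnormal"))

    rows = []
    for s in seeds:
        cohort = generate_counts(spec.with_seed(int(s)))
        frame, results = run_model2(cohort.counts, prior, n_draws, seed=int(s))
        m1 = run_model1(cohort.counts.to_binary(), prior=prior,
                        n_draws=n_draws, seed=int(s))

        covered = total = 0
        for _, row in frame.iterrows():
            if row["status"] not in ("ok", "reference"):
                continue
            i = BWCategory[row["bw"]] - 1
            j = _LG_INDEX[row["lg"]]
            for race in Race:
                if cohort.counts.births[race.axis, i, j] < min_cell_births:
                    continue
                key = race.name.lower()
                total += 1
                truth = spec.mortality[race.axis, i, j]
                if row[f"po_{key}_lo"] <= truth <= row[f"po_{key}_hi"]:
                    covered += 1

        dom_res = results.get(dom)
        te_res = next(iter(results.values()))
        rows.append({
            "seed": int(s),
            "po_covered": covered,
            "po_checked": total,
            "te_covered": te_res.te.lo2_5 <= te_true <= te_res.te.hi97_5,
            "pa_covered": (dom_res is not None
                           and dom_res.pa.lo2_5 <= pa_true <= dom_res.pa.hi97_5),
            "pa_binary_covered": m1[2].pa.lo2_5 <= pa_true_binary <= m1[2].pa.hi97_5,
        })
    frame = pd.DataFrame(rows)
    frame.attrs.update({"te_true": te_true, "pa_true": pa_true,
                        "dominant_cell": dom, "pa_true_binary": pa_true_binary})
    return frame
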