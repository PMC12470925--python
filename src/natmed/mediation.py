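"""Potential-outcome mediation calculus for the race / birth-condition model.

The exposure is the binary race group, the mediator is the joint birthweight x
length-of-gestation category (an interaction node, so no direct/indirect
decomposition is attempted).  The quantities computed here are

* the total effect TE, the difference of race-marginal mortality rates
  (Black minus non-Black), and its ratio form, the marginal relative risk;
* controlled direct effects CDE: the racial difference that would remain if a
  control strategy replaced the mortality rate of targeted strata with the
  rate of a reference (normal) stratum;
* the percentage attributable PA = 100 * (TE - CDE) / TE, the share of the
  disparity removed by the control.

A control strategy is propagated through four steps, all carried drawwise on
Monte-Carlo posterior samples so every derived quantity has a full posterior:

1. the controlled death count in each targeted stratum,
   ``s_r = births_in_stratum * PO_reference`` (real-valued, not rounded);
2. the counterfactual population death count per race,
   ``p_r = race_deaths - sum(stratum_deaths - s_r)`` over targeted strata;
3. the counterfactual race rate ``new_po = p_r / race_births``;
4. ``CDE = new_po[Black] - new_po[non-Black]`` and PA as above.

All draws for one run share a single random stream, so differences and ratios
are coherent draw by draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .categorize import (
    BINARY_NORMAL,
    BWCategory,
    LGCategory,
    Race,
    StrataCounts,
    _LG_LABELS,
)
from .posterior import (
    BETA_1_10,
    DEFAULT_N_DRAWS,
    JEFFREYS,
    PosteriorDraws,
    PosteriorSummary,
    PriorSpec,
    SeedLike,
    _rng,
    posterior_draws,
    race_marginal_po,
    summarize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ControlStrategy",
    "MediationResult",
    "total_effect",
    "relative_risk",
    "controlled_stratum_counts",
    "counterfactual_population_counts",
    "new_po",
    "cde",
    "percent_attributable",
    "propagate_control",
    "incidence_relative_risk",
    "conditional_rate_ratio",
    "run_control",
    "run_model1",
    "run_model2",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class ControlStrategy:
    """Which strata a control targets and which stratum supplies the rate.

    ``target`` is either one specific 0-based (bw, lg) cell, or one of the
    named selectors ``"abnormal_bw"`` (every stratum with abnormal
    birthweight), ``"abnormal_lg"``, or ``"all_abnormal"`` (every stratum
    except the joint-normal reference).  ``reference_rule`` is
    ``"joint_normal"`` (all targeted strata take the (normal BW, term) rate)
    or ``"match_other_mediator"`` (a stratum keeps its other mediator's level
    and only the abnormal mediator is moved to normal — the minimal
    single-mediator intervention).
    """

    scheme: str
    target: Union[str, Cell]
    reference_rule: str = "joint_normal"

    def __post_init__(self) -> None:
        if self.scheme not in ("binary", "five_by_five"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.reference_rule not in ("joint_normal", "match_other_mediator"):
            raise ValueError(f"unknown reference_rule {self.reference_rule!r}")
        if isinstance(self.target, str):
            if self.target not in ("abnormal_bw", "abnormal_lg", "all_abnormal"):
                raise ValueError(f"unknown target {self.target!r}")
            if self.target == "all_abnormal" and self.reference_rule != "joint_normal":
                raise ValueError("all_abnormal control requires the joint_normal rule")
        else:
            ref = self._reference_cell()
            if tuple(self.target) == ref:
                raise ValueError("cannot target the reference stratum itself "
                                 "with a specific-cell control")
            if self.scheme == "five_by_five" and self.reference_rule != "joint_normal":
                raise ValueError("specific-cell control uses the joint_normal rule")

    def _k(self) -> int:
        return 2 if self.scheme == "binary" else 5

    def _reference_cell(self) -> Cell:
        if self.scheme == "binary":
            return (BINARY_NORMAL, BINARY_NORMAL)
        return (BWCategory.NBW - 1, LGCategory.TD - 1)

    def targeted_cells(self) -> list[Cell]:
        k = self._k()
        ref_bw, ref_lg = self._reference_cell()
        if isinstance(self.target, tuple):
            return [tuple(self.target)]
        cells: list[Cell] = []
        for i in range(k):
            for j in range(k):
                if self.target == "abnormal_bw" and i != ref_bw:
                    cells.append((i, j))
                elif self.target == "abnormal_lg" and j != ref_lg:
                    cells.append((i, j))
                elif self.target == "all_abnormal" and (i, j) != (ref_bw, ref_lg):
                    cells.append((i, j))
        return cells

    def reference_for(self, cell: Cell) -> Cell:
        """Reference stratum supplying the controlled rate for ``cell``."""
        ref_bw, ref_lg = self._reference_cell()
        if self.reference_rule == "joint_normal":
            return (ref_bw, ref_lg)
        i, j = cell
        if self.target == "abnormal_bw":
            return (ref_bw, j)
        if self.target == "abnormal_lg":
            return (i, ref_lg)
        # specific binary cell under match rule: move whichever mediator is
        # abnormal; both abnormal maps to joint normal
        return (ref_bw if i != ref_bw else i, ref_lg if j != ref_lg else j)

    def describe(self) -> str:
        if isinstance(self.target, tuple):
            i, j = self.target
            if self.scheme == "five_by_five":
                return f"{BWCategory(i + 1).name}/{_LG_LABELS[LGCategory(j + 1)]}"
            return f"cell({i},{j})"
        return {"abnormal_bw": "birthweight", "abnormal_lg": "length of gestation",
                "all_abnormal": "birthweight and length of gestation"}[self.target]


@dataclass
class MediationResult:
    """TE, CDE, PA and the intermediate counterfactual quantities of one run."""

    strategy: ControlStrategy
    te: PosteriorSummary
    cde: PosteriorSummary
    pa: PosteriorSummary
    mediated: PosteriorSummary  # TE - CDE
    new_po: dict[Race, PosteriorSummary]
    p_r: dict[Race, PosteriorSummary]
    s_r: dict[Cell, dict[Race, PosteriorSummary]]
    te_draws: PosteriorDraws = field(repr=False, default=None)  # type: ignore
    cde_draws: PosteriorDraws = field(repr=False, default=None)  # type: ignore
    pa_draws: PosteriorDraws = field(repr=False, default=None)  # type: ignore


# ---------------------------------------------------------------------------
# elemental drawwise operations


def total_effect(
    counts: StrataCounts,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
) -> PosteriorDraws:
    """Drawwise Black-minus-non-Black difference of marginal mortality POs."""
    if (counts.race_births == 0).any():
        raise ValueError("total effect undefined: a race group has zero births")
    rng = _rng(seed)
    po_nb = race_marginal_po(counts, Race.NON_BLACK, prior, n_draws, rng)
    po_b = race_marginal_po(counts, Race.BLACK, prior, n_draws, rng)
    return PosteriorDraws(po_b.values - po_nb.values, label="TE")


def relative_risk(
    counts: StrataCounts,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
) -> PosteriorDraws:
    """Drawwise Black / non-Black ratio of marginal mortality POs."""
    if (counts.race_births == 0).any():
        raise ValueError("relative risk undefined: a race group has zero births")
    rng = _rng(seed)
    po_nb = race_marginal_po(counts, Race.NON_BLACK, prior, n_draws, rng)
    po_b = race_marginal_po(counts, Race.BLACK, prior, n_draws, rng)
    return PosteriorDraws(po_b.values / po_nb.values, label="RR")


def controlled_stratum_counts(
    counts: StrataCounts,
    strategy: ControlStrategy,
    reference_po: dict[Cell, dict[Race, np.ndarray]],
) -> dict[Cell, dict[Race, np.ndarray]]:
    """Controlled death counts s_r per targeted stratum and race (drawwise).

    ``reference_po[ref_cell][race]`` holds the posterior draws of the
    reference stratum's PO.  s_r is kept real-valued.  A targeted stratum
    with no births yields s_r = 0 (the control is a no-op there).
    """
    out: dict[Cell, dict[Race, np.ndarray]] = {}
    for cell in strategy.targeted_cells():
        ref = strategy.reference_for(cell)
        per_race: dict[Race, np.ndarray] = {}
        for race in Race:
            n_cell = counts.births[race.axis, cell[0], cell[1]]
            if n_cell == 0:
                logger.info("control no-op: stratum %s has no %s births",
                            cell, race.name)
                per_race[race] = np.zeros_like(np.asarray(reference_po[ref][race]))
            else:
                per_race[race] = n_cell * np.asarray(reference_po[ref][race])
        out[cell] = per_race
    return out


def counterfactual_population_counts(
    counts: StrataCounts,
    s_r: dict[Cell, dict[Race, np.ndarray]],
) -> dict[Race, np.ndarray]:
    """Counterfactual population death count p_r per race (drawwise)."""
    out: dict[Race, np.ndarray] = {}
    for race in Race:
        delta = 0.0
        for cell, per_race in s_r.items():
            r_cell = counts.deaths[race.axis, cell[0], cell[1]]
            delta = delta + (r_cell - per_race[race])
        out[race] = counts.race_deaths[race.axis] - delta
    return out


def new_po(p_r: dict[Race, np.ndarray], counts: StrataCounts) -> dict[Race, np.ndarray]:
    """Counterfactual race mortality rates p_r / race_births (drawwise)."""
    if (counts.race_births == 0).any():
        raise ValueError("race birth totals must be positive")
    return {race: np.asarray(p_r[race]) / counts.race_births[race.axis]
            for race in Race}


def cde(new_po_draws: dict[Race, np.ndarray]) -> np.ndarray:
    """Controlled direct effect: Black minus non-Black counterfactual rate."""
    return np.asarray(new_po_draws[Race.BLACK]) - np.asarray(new_po_draws[Race.NON_BLACK])


def percent_attributable(te_draws: np.ndarray, cde_draws: np.ndarray) -> np.ndarray:
    """PA = 100 * (TE - CDE) / TE, drawwise; zero-TE draws are excluded."""
    te_arr = np.asarray(te_draws, dtype=float)
    cde_arr = np.broadcast_to(np.asarray(cde_draws, dtype=float), te_arr.shape)
    nonzero = te_arr != 0
    n_zero = int(np.size(te_arr) - np.count_nonzero(nonzero))
    if n_zero:
        logger.warning("excluded %d draws with TE = 0 from PA", n_zero)
        te_arr, cde_arr = te_arr[nonzero], cde_arr[nonzero]
    return 100.0 * (te_arr - cde_arr) / te_arr


def propagate_control(
    race_deaths: Sequence[float],
    race_births: Sequence[float],
    targeted_deaths: Sequence[float],
    s_r,
):
    """One-stratum control propagation on plain numbers or draw arrays.

    ``race_deaths``/``race_births``/``targeted_deaths`` are (non-Black, Black)
    pairs; ``s_r`` a matching pair of controlled stratum counts (scalars for a
    plug-in evaluation, draw vectors for a full posterior).  Returns
    ``(p_r, new_po, cde)`` with p_r and new_po as (non-Black, Black) pairs.
    Useful for worked examples where the controlled stratum counts are given
    directly rather than derived from a reference posterior.
    """
    p_r = tuple(np.asarray(race_deaths[i]) - (np.asarray(targeted_deaths[i]) - np.asarray(s_r[i]))
                for i in range(2))
    npo = tuple(p_r[i] / np.asarray(race_births[i], dtype=float) for i in range(2))
    return p_r, npo, npo[1] - npo[0]


# ---------------------------------------------------------------------------
# descriptive per-stratum contrasts


def incidence_relative_risk(
    counts: StrataCounts,
    cell: Cell,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
    prior: PriorSpec = JEFFREYS,
) -> PosteriorDraws:
    """Black / non-Black ratio of the probability of being born in a stratum.

    Stratum membership per race is modelled as binomial out of the race's
    births with an independent Jeffreys-type conjugate posterior.  If the
    stratum is unobserved in one race the ratio's interval is prior-driven
    and the draws are labelled unstable.
    """
    if (counts.race_births == 0).any():
        raise ValueError("race totals must be positive")
    rng = _rng(seed)
    props = {}
    unstable = False
    for race in Race:
        m = int(counts.births[race.axis, cell[0], cell[1]])
        n_tot = int(counts.race_births[race.axis])
        if m == 0:
            unstable = True
        props[race] = posterior_draws(m, n_tot, prior, n_draws, rng).values
    label = f"incidence RR {cell}"
    if unstable:
        logger.warning("incidence RR for stratum %s unstable: unobserved in one race", cell)
        label += " [unstable]"
    return PosteriorDraws(props[Race.BLACK] / props[Race.NON_BLACK], label=label)


def conditional_rate_ratio(
    po_black: PosteriorDraws, po_nonblack: PosteriorDraws
) -> PosteriorDraws:
    """Within-stratum Black / non-Black mortality rate ratio, drawwise."""
    return PosteriorDraws(po_black.values / po_nonblack.values,
                          label="conditional rate ratio")


# ---------------------------------------------------------------------------
# full runs


def run_control(
    counts: StrataCounts,
    strategy: ControlStrategy,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
    keep_draws: bool = True,
) -> MediationResult:
    """Propagate one control strategy end to end with a shared draw stream."""
    rng = _rng(seed)
    te_draws = total_effect(counts, prior, n_draws, rng)

    ref_cells = {strategy.reference_for(c) for c in strategy.targeted_cells()}
    reference_po: dict[Cell, dict[Race, np.ndarray]] = {}
    for ref in sorted(ref_cells):
        reference_po[ref] = {
            race: posterior_draws(
                int(counts.deaths[race.axis, ref[0], ref[1]]),
                int(counts.births[race.axis, ref[0], ref[1]]),
                prior, n_draws, rng,
            ).values
            for race in Race
        }

    s_r = controlled_stratum_counts(counts, strategy, reference_po)
    p_r = counterfactual_population_counts(counts, s_r)
    npo = new_po(p_r, counts)
    cde_draws = cde(npo)
    pa_draws = percent_attributable(te_draws.values, cde_draws)

    def _sum(values: np.ndarray) -> PosteriorSummary:
        return summarize(PosteriorDraws(values))

    result = MediationResult(
        strategy=strategy,
        te=_sum(te_draws.values),
        cde=_sum(cde_draws),
        pa=_sum(pa_draws),
        mediated=_sum(te_draws.values - cde_draws),
        new_po={race: _sum(npo[race]) for race in Race},
        p_r={race: _sum(p_r[race]) for race in Race},
        s_r={c: {race: _sum(v[race]) for race in Race} for c, v in s_r.items()},
    )
    if keep_draws:
        result.te_draws = te_draws
        result.cde_draws = PosteriorDraws(cde_draws, label="CDE")
        result.pa_draws = PosteriorDraws(pa_draws, label="PA")
    return result


def run_model1(
    counts_binary: StrataCounts,
    strategies: Optional[Sequence[ControlStrategy]] = None,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
) -> list[MediationResult]:
    """Binary-mediator mediation: control abnormal BW, abnormal LG, or both.

    The single-mediator rows use the ``match_other_mediator`` reference rule
    by default (moving only the abnormal mediator to normal); the joint row
    controls every non-reference stratum to the joint-normal rate.
    """
    if counts_binary.scheme != "binary":
        raise ValueError("run_model1 requires binary-scheme counts")
    if strategies is None:
        strategies = [
            ControlStrategy("binary", "abnormal_bw", "match_other_mediator"),
            ControlStrategy("binary", "abnormal_lg", "match_other_mediator"),
            ControlStrategy("binary", "all_abnormal", "joint_normal"),
        ]
    rng = _rng(seed)
    return [run_control(counts_binary, s, prior, n_draws, rng) for s in strategies]


def run_model2(
    counts: StrataCounts,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
) -> tuple[pd.DataFrame, dict[Cell, MediationResult]]:
    """Per-stratum analysis on the 5x5 scheme.

    For every observed stratum except the joint-normal reference: the PO per
    race, the incidence relative risk, the conditional mortality rate ratio,
    and PA under the single-cell joint-normal control.  Unobserved strata are
    flagged ``not_observed``; the reference stratum carries no PA.  Returns a
    tidy frame (one row per stratum) and the full per-cell results.
    """
    if counts.scheme != "five_by_five":
        raise ValueError("run_model2 requires five_by_five counts")
    rng = _rng(seed)

    ref = counts.reference_cell
    te_draws = total_effect(counts, prior, n_draws, rng)
    ref_po = {
        race: posterior_draws(
            int(counts.deaths[race.axis, ref[0], ref[1]]),
            int(counts.births[race.axis, ref[0], ref[1]]),
            prior, n_draws, rng,
        ).values
        for race in Race
    }

    rows = []
    results: dict[Cell, MediationResult] = {}
    observed = counts.observed()
    for i in range(5):
        for j in range(5):
            cell_ = (i, j)
            bw_lab = BWCategory(i + 1).name
            lg_lab = _LG_LABELS[LGCategory(j + 1)]
            row: dict = {"bw": bw_lab, "lg": lg_lab}
            for race in Race:
                row[f"births_{race.name.lower()}"] = int(counts.births[race.axis, i, j])
                row[f"deaths_{race.name.lower()}"] = int(counts.deaths[race.axis, i, j])
            if not observed[i, j]:
                row["status"] = "not_observed"
                rows.append(row)
                continue
            row["status"] = "reference" if cell_ == ref else "ok"

            po = {
                race: posterior_draws(
                    int(counts.deaths[race.axis, i, j]),
                    int(counts.births[race.axis, i, j]),
                    prior, n_draws, rng,
                )
                for race in Race
            }
            for race in Race:
                s = summarize(po[race])
                key = race.name.lower()
                row[f"po_{key}"], row[f"po_{key}_lo"], row[f"po_{key}_hi"] = s.as_tuple()

            irr = incidence_relative_risk(counts, cell_, n_draws, rng)
            s = summarize(irr)
            row["incidence_rr"], row["incidence_rr_lo"], row["incidence_rr_hi"] = s.as_tuple()
            row["incidence_rr_unstable"] = "[unstable]" in irr.label

            s = summarize(conditional_rate_ratio(po[Race.BLACK], po[Race.NON_BLACK]))
            row["cond_ratio"], row["cond_ratio_lo"], row["cond_ratio_hi"] = s.as_tuple()

            if cell_ != ref:
                s_r = controlled_stratum_counts(
                    counts,
                    ControlStrategy("five_by_five", cell_),
                    {ref: ref_po},
                )
                p_r = counterfactual_population_counts(counts, s_r)
                npo = new_po(p_r, counts)
                cde_draws = cde(npo)
                pa_draws = percent_attributable(te_draws.values, cde_draws)
                res = MediationResult(
                    strategy=ControlStrategy("five_by_five", cell_),
                    te=summarize(te_draws),
                    cde=summarize(PosteriorDraws(cde_draws)),
                    pa=summarize(PosteriorDraws(pa_draws)),
                    mediated=summarize(PosteriorDraws(te_draws.values - cde_draws)),
                    new_po={r_: summarize(PosteriorDraws(npo[r_])) for r_ in Race},
                    p_r={r_: summarize(PosteriorDraws(p_r[r_])) for r_ in Race},
                    s_r={cell_: {r_: summarize(PosteriorDraws(s_r[cell_][r_]))
                                 for r_ in Race}},
                    te_draws=te_draws,
                    cde_draws=PosteriorDraws(cde_draws, label="CDE"),
                    pa_draws=PosteriorDraws(pa_draws, label="PA"),
                )
                results[cell_] = res
                row["pa"], row["pa_lo"], row["pa_hi"] = res.pa.as_tuple()
                row["cde"], row["cde_lo"], row["cde_hi"] = res.cde.as_tuple()
            rows.append(row)

    return pd.DataFrame(rows), results
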