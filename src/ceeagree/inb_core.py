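"""Per-source cost-effectiveness estimation.

Net benefits, incremental cost/effect, the ICER with cost-effectiveness
plane quadrant classification, the incremental net benefit (INB) point
estimate with its standard error, and cost-effectiveness acceptability
curves (CEACs).

The INB at willingness-to-pay threshold λ is β(λ) = λ·ΔE − ΔC, where ΔE
is the incremental effect (oriented so that larger is better) and ΔC the
incremental cost, intervention minus control. Its standard error follows
from the per-patient net benefit nb = λ·e − c: the two arms are
independent, so Var(β̂) = s²_nb,int/n_int + s²_nb,ctl/n_ctl.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial_data import (
    CONTROL,
    INTERVENTION,
    ArmSummary,
    InsufficientDataError,
    PairedTrialData,
    ValidationError,
    summarize_arm,
)


@dataclass(frozen=True)
class INBEstimate:
    """Mean incremental net benefit at one threshold, for one source."""

    source: int
    lam: float
    beta_hat: float
    se: float
    delta_cost: float
    delta_effect: float
    summary_control: ArmSummary
    summary_intervention: ArmSummary


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness ratio with quadrant classification.

    The ICER is ΔC/ΔE; its meaning depends on the quadrant of the
    cost-effectiveness plane the point (ΔE, ΔC) occupies, so the ratio is
    reported together with the quadrant and a dominance note. A zero
    incremental effect leaves the ratio undefined (flagged, not raised).
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    quadrant: str
    note: str


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if not math.isfinite(lam) or lam < 0:
        raise ValidationError(f"threshold lambda must be finite and >= 0, got {lam!r}")
    return lam


def net_benefit(cost: float, effect: float, lam: float) -> float:
    """Net monetary benefit λ·effect − cost.

    ``effect`` must already be oriented so that larger is better.
    """
    lam = _check_lambda(lam)
    if not (math.isfinite(cost) and math.isfinite(effect)):
        raise ValidationError("cost and effect must be finite")
    return lam * effect - cost


def oriented_effect(outcome, adverse: bool):
    """Orient a recorded event indicator so that larger means better.

    For an adverse event (e.g. sepsis) the benefit is the event *averted*:
    the oriented effect is 1 − outcome. For a beneficial outcome the
    indicator is returned unchanged. Accepts scalars or arrays.
    """
    outcome = np.asarray(outcome, dtype=float)
    res = 1.0 - outcome if adverse else outcome
    return float(res) if res.ndim == 0 else res


def _oriented_arm_arrays(
    data: PairedTrialData, source: int, arm: str
) -> tuple[np.ndarray, np.ndarray]:
    cost, outcome = data.arm_arrays(source, arm)
    return cost, oriented_effect(outcome, data.adverse_outcome)


def incremental_cost(data: PairedTrialData, source: int) -> float:
    """Mean intervention-arm cost minus mean control-arm cost."""
    return (
        summarize_arm(data, source, INTERVENTION).mean_cost
        - summarize_arm(data, source, CONTROL).mean_cost
    )


def incremental_effect(data: PairedTrialData, source: int) -> float:
    """Incremental effect, oriented so that positive favours intervention.

    With an adverse outcome this is the control-arm event proportion minus
    the intervention-arm event proportion (events averted); otherwise the
    intervention-minus-control difference of raw effect means. Equals the
    difference of oriented-effect means in all cases.
    """
    s_int = summarize_arm(data, source, INTERVENTION)
    s_ctl = summarize_arm(data, source, CONTROL)
    raw = s_int.mean_effect - s_ctl.mean_effect
    return -raw if data.adverse_outcome else raw


def classify_quadrant(delta_cost: float, delta_effect: float) -> tuple[str, str]:
    """Cost-effectiveness plane quadrant and dominance note for (ΔE, ΔC)."""
    if delta_effect == 0 or delta_cost == 0:
        return "boundary", "on an axis of the cost-effectiveness plane"
    if delta_effect > 0 and delta_cost > 0:
        return "NE", "more effective, more costly"
    if delta_effect > 0 and delta_cost < 0:
        return "SE", "intervention dominant (more effective, less costly)"
    if delta_effect < 0 and delta_cost > 0:
        return "NW", "intervention dominated (less effective, more costly)"
    return "SW", "less effective, less costly"


def icer(data: PairedTrialData, source: int) -> ICERResult:
    """ICER = ΔC/ΔE with quadrant classification.

    ΔE = 0 yields an undefined ratio with a ``boundary`` quadrant rather
    than an exception.
    """
    dc = incremental_cost(data, source)
    de = incremental_effect(data, source)
    quadrant, note = classify_quadrant(dc, de)
    ratio = dc / de if de != 0 else None
    return ICERResult(delta_cost=dc, delta_effect=de, icer=ratio, quadrant=quadrant, note=note)


def per_patient_net_benefit(
    data: PairedTrialData, source: int, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient net benefits (intervention array, control array)."""
    lam = _check_lambda(lam)
    out = []
    for arm in (INTERVENTION, CONTROL):
        cost, eff = _oriented_arm_arrays(data, source, arm)
        out.append(lam * eff - cost)
    return out[0], out[1]


def inb_estimate(data: PairedTrialData, source: int, lam: float) -> INBEstimate:
    """Mean INB and its standard error at threshold λ for one source.

    β̂ = mean per-patient net benefit in the intervention arm minus the
    control arm; se² = s²_nb,int/n_int + s²_nb,ctl/n_ctl. This equals the
    moment decomposition Σ_arms [λ²·var(E) + var(C) − 2λ·cov(C, E)]/n_arm
    with the oriented effect (verified by property test).
    """
    nb_int, nb_ctl = per_patient_net_benefit(data, source, lam)
    if nb_int.size < 2 or nb_ctl.size < 2:
        raise InsufficientDataError("each arm needs at least 2 records for an SE")
    beta = float(nb_int.mean() - nb_ctl.mean())
    se2 = nb_int.var(ddof=1) / nb_int.size + nb_ctl.var(ddof=1) / nb_ctl.size
    return INBEstimate(
        source=source,
        lam=float(lam),
        beta_hat=beta,
        se=float(np.sqrt(se2)),
        delta_cost=incremental_cost(data, source),
        delta_effect=incremental_effect(data, source),
        summary_control=summarize_arm(data, source, CONTROL),
        summary_intervention=summarize_arm(data, source, INTERVENTION),
    )


def _stratified_indices(
    rng: np.random.Generator, n: int, n_boot: int
) -> np.ndarray:
    return rng.integers(0, n, size=(n_boot, n))


def bootstrap_deltas(
    data: PairedTrialData, source: int, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Arm-stratified bootstrap of (ΔE, ΔC), whole patient rows resampled.

    Returns arrays of shape (n_boot,): incremental oriented effect and
    incremental cost per replicate. Arm sizes are preserved.
    """
    means = {}
    for arm in (INTERVENTION, CONTROL):
        cost, eff = _oriented_arm_arrays(data, source, arm)
        idx = _stratified_indices(rng, cost.size, n_boot)
        means[arm] = (cost[idx].mean(axis=1), eff[idx].mean(axis=1))
    d_cost = means[INTERVENTION][0] - means[CONTROL][0]
    d_eff = means[INTERVENTION][1] - means[CONTROL][1]
    return d_eff, d_cost


def ce_plane_cloud(
    data: PairedTrialData, source: int, n_boot: int, seed: int
) -> np.ndarray:
    """Bootstrap (ΔE, ΔC) cloud for a cost-effectiveness plane scatter.

    Returns an (n_boot, 2) array of (delta_effect, delta_cost) replicates.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    d_eff, d_cost = bootstrap_deltas(data, source, n_boot, rng)
    return np.column_stack([d_eff, d_cost])


def ceac(
    data: PairedTrialData,
    source: int,
    lambda_grid: Sequence[float],
    n_boot: int,
    seed: int,
    method: str = "bootstrap",
) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each λ on the grid, the probability that the intervention is
    cost-effective: the proportion of arm-stratified bootstrap replicates
    with β̂*(λ) = λ·ΔE* − ΔC* > 0. ``method="normal"`` instead evaluates
    the normal approximation Φ(β̂/se) at each λ.
    """
    grid = [_check_lambda(l) for l in lambda_grid]
    if len(grid) == 0:
        raise ValidationError("lambda grid must be non-empty")
    if method == "normal":
        from scipy.stats import norm

        probs = []
        for lam in grid:
            est = inb_estimate(data, source, lam)
            probs.append(1.0 if est.se == 0 and est.beta_hat > 0
                         else 0.5 if est.se == 0
                         else float(norm.cdf(est.beta_hat / est.se)))
        return np.asarray(probs)
    if method != "bootstrap":
        raise ValidationError(f"unknown CEAC method {method!r}")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    d_eff, d_cost = bootstrap_deltas(data, source, n_boot, rng)
    lam_arr = np.asarray(grid)[:, None]
    beta = lam_arr * d_eff[None, :] - d_cost[None, :]
    return (beta > 0).mean(axis=1)
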