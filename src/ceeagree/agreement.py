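"""Agreement statistics between two data sources' INB endpoints.

Three statistics compare the mean incremental net benefit (INB) estimated
from two patient-level data sources at a willingness-to-pay threshold λ:

* **Difference in means** ω = β̂₂ − β̂₁ with a Z test. Because the two
  sources describe the same patients, the INBs are correlated; the
  variance of ω is σ²_β1 + σ²_β2 − 2·cov(β̂₁, β̂₂). With complete paired
  rows this is realized exactly by working with the per-patient paired
  net-benefit differences d_j = nb₂ⱼ − nb₁ⱼ.
* **Miscoverage probability**: the proportion of bootstrap replicates of
  the *test* data whose Wald confidence interval for the INB excludes the
  *referent* source's point estimate. Values near the nominal α indicate
  the test source could stand in for the referent.
* **Concordance correlation coefficient** ρ_c (Lin's agreement measure
  adapted to INB endpoints): ρ_c = 2·cov(β̂₁, β̂₂) / [(β₂−β₁)² + σ²_β1 +
  σ²_β2], decomposed as Pearson precision ρ times accuracy C_b. A
  confidence interval comes from Fisher-transforming bootstrap replicates;
  a one-sided test compares ρ̂_c against a least-acceptable threshold
  ρ_c0, either fixed (0.4/0.65/0.8 are common conventions) or derived as
  C_b·√(ρ² − x) for an acceptable precision loss x.

All bootstraps resample whole patient rows (keeping both sources' values
together), stratified by arm with arm sizes preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_data import (
    CONTROL,
    INTERVENTION,
    InsufficientDataError,
    PairedTrialData,
    ValidationError,
)
from .inb_core import inb_estimate, per_patient_net_benefit, _check_lambda


class UndefinedThresholdError(ValidationError):
    """ρ² < x: the precision-loss concordance threshold is undefined."""


@dataclass(frozen=True)
class DifferenceResult:
    """Difference in mean INBs between sources at one threshold."""

    lam: float
    beta_1: float
    beta_2: float
    omega: float
    se_omega: float
    z: float
    p_two_sided: float
    exact_agreement: bool
    se_1: float = float("nan")
    se_2: float = float("nan")


@dataclass(frozen=True)
class MiscoverageResult:
    """Bootstrap miscoverage of the test source's CI w.r.t. the referent."""

    referent: int
    test: int
    lam: float
    alpha: float
    n_boot: int
    miscoverage: float
    seed: int
    calibration: bool  # referent == test (self-comparison, ≈ alpha expected)


@dataclass(frozen=True)
class ConcordanceResult:
    """Adapted concordance correlation between the two sources' INBs."""

    lam: float
    rho_c: float
    rho: float
    c_b: float
    z_rho_c: float
    se_z: float
    ci_low: float
    ci_high: float
    rho_c0: float
    p_one_sided: float
    n_boot: int
    seed: int
    degenerate: bool  # identical sources: point CI, ρ̂_c = 1


@dataclass
class AgreementCurve:
    """All three agreement statistics evaluated over a λ grid."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def fisher_z(rho_c: float) -> float:
    """Fisher Z transform ½·ln((1+r)/(1−r)); requires |r| < 1."""
    if not abs(rho_c) < 1:
        raise ValidationError(f"Fisher Z requires |r| < 1, got {rho_c!r}")
    return float(np.arctanh(rho_c))


def fisher_z_inv(z: float) -> float:
    """Inverse Fisher transform tanh(z)."""
    return float(np.tanh(z))


def ccc_threshold(rho: float, c_b: float, x_loss: float) -> float:
    """Least-acceptable concordance ρ_c0 = C_b·√(ρ² − x).

    ``x_loss`` is the acceptable fractional loss in precision (e.g. 0.05
    for 5%). Undefined when ρ² < x.
    """
    if not (0 < c_b <= 1 + 1e-9):  # tolerate float noise at the c_b = 1 boundary
        raise ValidationError(f"c_b must be in (0, 1], got {c_b!r}")
    c_b = min(c_b, 1.0)
    if not (0 <= x_loss < 1):
        raise ValidationError(f"x_loss must be in [0, 1), got {x_loss!r}")
    if rho * rho < x_loss:
        raise UndefinedThresholdError(
            f"rho^2 = {rho * rho:.4f} < x_loss = {x_loss}; threshold undefined"
        )
    return float(c_b * math.sqrt(rho * rho - x_loss))


def _paired_nb(data: PairedTrialData, lam: float):
    """Per-arm paired net-benefit arrays: {arm: (nb1, nb2)}."""
    nb1_int, nb1_ctl = per_patient_net_benefit(data, 1, lam)
    nb2_int, nb2_ctl = per_patient_net_benefit(data, 2, lam)
    return {INTERVENTION: (nb1_int, nb2_int), CONTROL: (nb1_ctl, nb2_ctl)}


def difference_from_summaries(
    beta_1: float, beta_2: float, se_omega: float, lam: float = float("nan")
) -> DifferenceResult:
    """Z test of ω = β₂ − β₁ from summary-level estimates.

    For use when only the mean INBs and the standard error of their
    difference are available (e.g. published tables). ``se_omega`` must
    already account for the between-source covariance.
    """
    if se_omega < 0:
        raise ValidationError("se_omega must be >= 0")
    omega = beta_2 - beta_1
    if se_omega == 0:
        exact = omega == 0
        z = 0.0 if exact else math.copysign(math.inf, omega)
        p = 1.0 if exact else 0.0
        return DifferenceResult(lam, beta_1, beta_2, omega, 0.0, z, p, exact)
    z = omega / se_omega
    p = float(2 * norm.sf(abs(z)))
    return DifferenceResult(lam, beta_1, beta_2, omega, se_omega, z, p, False)


def inb_difference(data: PairedTrialData, lam: float) -> DifferenceResult:
    """Z test of the difference in mean INBs between the two sources.

    Works on the per-patient paired net-benefit differences d_j = nb₂ⱼ −
    nb₁ⱼ: ω̂ = mean(d | intervention) − mean(d | control) and
    se²_ω = s²_d,int/n_int + s²_d,ctl/n_ctl, which realizes the
    covariance-corrected variance through within-patient pairing. If every
    d_j is zero the sources agree exactly: ω = 0, z = 0, p = 1.
    """
    lam = _check_lambda(lam)
    est1 = inb_estimate(data, 1, lam)
    est2 = inb_estimate(data, 2, lam)
    nb = _paired_nb(data, lam)
    d_int = nb[INTERVENTION][1] - nb[INTERVENTION][0]
    d_ctl = nb[CONTROL][1] - nb[CONTROL][0]
    omega = float(d_int.mean() - d_ctl.mean())
    se2 = d_int.var(ddof=1) / d_int.size + d_ctl.var(ddof=1) / d_ctl.size
    se = float(np.sqrt(se2))
    if np.all(d_int == 0) and np.all(d_ctl == 0):
        return DifferenceResult(
            lam, est1.beta_hat, est2.beta_hat, 0.0, 0.0, 0.0, 1.0, True,
            est1.se, est2.se,
        )
    if se == 0:
        z = 0.0 if omega == 0 else math.copysign(math.inf, omega)
        p = 1.0 if omega == 0 else 0.0
    else:
        z = omega / se
        p = float(2 * norm.sf(abs(z)))
    return DifferenceResult(
        lam, est1.beta_hat, est2.beta_hat, omega, se, float(z), p, False,
        est1.se, est2.se,
    )


def equivalence_test(diff: DifferenceResult, delta: float) -> float:
    """TOST equivalence p-value for |ω| < δ.

    p = max[1 − Φ((ω + δ)/se), 1 − Φ((δ − ω)/se)]; equivalence at level α
    is declared when p ≤ α. Exact agreement (se = 0, ω = 0) returns 0 by
    convention.
    """
    if delta <= 0:
        raise ValidationError("equivalence margin delta must be > 0")
    if diff.exact_agreement:
        return 0.0
    if diff.se_omega == 0:
        return 0.0 if abs(diff.omega) < delta else 1.0
    p_lower = float(norm.sf((diff.omega + delta) / diff.se_omega))
    p_upper = float(norm.sf((delta - diff.omega) / diff.se_omega))
    return max(p_lower, p_upper)


def _bootstrap_arm_moments(
    nb1: np.ndarray, nb2: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Replicate-wise means, variances and covariance of paired nb arrays.

    ``idx`` has shape (S, n); moments use n−1 denominators.
    """
    n = idx.shape[1]
    x = nb1[idx]
    y = nb2[idx]
    mx = x.mean(axis=1)
    my = y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    cov = ((x * y).mean(axis=1) - mx * my) * (n / (n - 1))
    return mx, my, vx, vy, cov


def miscoverage(
    data: PairedTrialData,
    referent: int,
    test: int,
    lam: float,
    n_boot: int,
    alpha: float,
    seed: int,
) -> MiscoverageResult:
    """Bootstrap miscoverage of the test source against the referent.

    β̂_ref is computed once from the full data. Each of the S replicates
    resamples patients with replacement (stratified by arm, arm sizes
    preserved), recomputes the test source's β̂* and analytic se*, forms
    the Wald interval β̂* ± z_{1−α/2}·se*, and the miscoverage is the
    fraction of intervals that exclude β̂_ref. A referent equal to the
    test source is allowed for calibration (expected miscoverage ≈ α) and
    flagged in the result.
    """
    lam = _check_lambda(lam)
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    beta_ref = inb_estimate(data, referent, lam).beta_hat
    zcrit = norm.ppf(1 - alpha / 2)
    rng = np.random.default_rng(seed)

    nb_int, nb_ctl = per_patient_net_benefit(data, test, lam)
    stats = {}
    for name, nb in (("int", nb_int), ("ctl", nb_ctl)):
        idx = rng.integers(0, nb.size, size=(n_boot, nb.size))
        vals = nb[idx]
        stats[name] = (vals.mean(axis=1), vals.var(axis=1, ddof=1) / nb.size)
    beta_star = stats["int"][0] - stats["ctl"][0]
    se_star = np.sqrt(stats["int"][1] + stats["ctl"][1])
    lo = beta_star - zcrit * se_star
    hi = beta_star + zcrit * se_star
    outside = (beta_ref < lo) | (beta_ref > hi)
    return MiscoverageResult(
        referent=referent,
        test=test,
        lam=lam,
        alpha=alpha,
        n_boot=n_boot,
        miscoverage=float(outside.mean()),
        seed=seed,
        calibration=referent == test,
    )


def _ccc_point(data: PairedTrialData, lam: float) -> tuple[float, float, float, float, float]:
    """Point estimates (rho_c, rho, c_b, beta_1, beta_2) at threshold λ.

    σ̂²_βi and the cross-source covariance are those of the *mean* INB
    estimators: arm-wise moments of the per-patient net benefits divided
    by arm sizes and summed over the independent arms.
    """
    nb = _paired_nb(data, lam)
    var1 = var2 = cov12 = 0.0
    b1 = b2 = 0.0
    for arm, sign in ((INTERVENTION, 1.0), (CONTROL, -1.0)):
        nb1, nb2 = nb[arm]
        n = nb1.size
        if n < 2:
            raise InsufficientDataError("each arm needs at least 2 records")
        var1 += nb1.var(ddof=1) / n
        var2 += nb2.var(ddof=1) / n
        cov12 += float(np.cov(nb1, nb2, ddof=1)[0, 1]) / n
        b1 += sign * nb1.mean()
        b2 += sign * nb2.mean()
    denom = (b2 - b1) ** 2 + var1 + var2
    if denom == 0:
        raise ValidationError("both sources have zero sampling variability")
    rho_c = 2 * cov12 / denom
    sd1, sd2 = math.sqrt(var1), math.sqrt(var2)
    if sd1 == 0 or sd2 == 0:
        raise ValidationError(
            "a source shows zero sampling variability of the INB; "
            "Pearson precision undefined"
        )
    rho = cov12 / (sd1 * sd2)
    c_b = rho_c / rho if rho != 0 else float("nan")
    return float(rho_c), float(rho), float(c_b), float(b1), float(b2)


_CLIP = 1.0 - 1e-12


def concordance(
    data: PairedTrialData,
    lam: float,
    n_boot: int,
    seed: int,
    x_loss: float | None = 0.05,
    rho_c0_fixed: float | None = None,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Adapted concordance correlation between the two sources' INBs.

    Point estimates follow the moment formulas (see module docstring). The
    CI comes from an arm-stratified paired bootstrap: each replicate's
    ρ̂_c* is Fisher-transformed, se_z is the sample SD of the transformed
    replicates, and the interval tanh(z ± z_{1−α/2}·se_z) is reported.
    The one-sided test of ρ_c > ρ_c0 uses p = 1 − Φ((z(ρ̂_c) −
    z(ρ_c0))/se_z) with ρ_c0 either fixed or C_b·√(ρ̂² − x).

    Identical sources are a degenerate case: ρ̂_c = 1 with a point CI,
    flagged rather than raised. Replicates with |ρ̂_c*| = 1 are clipped to
    1 − 1e−12 before transforming.
    """
    lam = _check_lambda(lam)
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2 for a bootstrap CI")
    rho_c, rho, c_b, _, _ = _ccc_point(data, lam)

    nb = _paired_nb(data, lam)
    identical = all(np.array_equal(nb[arm][0], nb[arm][1]) for arm in nb)
    if identical:
        # exact agreement: ρ̂_c = 1 with a point CI; every bootstrap
        # replicate would reproduce it, so the resampling is skipped
        if rho_c0_fixed is not None:
            rho_c0 = float(rho_c0_fixed)
        else:
            if x_loss is None:
                raise ValidationError("provide x_loss or rho_c0_fixed")
            rho_c0 = ccc_threshold(1.0, 1.0, x_loss)
        return ConcordanceResult(
            lam=lam, rho_c=1.0, rho=1.0, c_b=1.0,
            z_rho_c=float(np.arctanh(_CLIP)), se_z=0.0,
            ci_low=1.0, ci_high=1.0, rho_c0=rho_c0,
            p_one_sided=0.0 if rho_c0 < 1.0 else 0.5,
            n_boot=n_boot, seed=seed, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    moments = {}
    for arm in (INTERVENTION, CONTROL):
        nb1, nb2 = nb[arm]
        idx = rng.integers(0, nb1.size, size=(n_boot, nb1.size))
        moments[arm] = (_bootstrap_arm_moments(nb1, nb2, idx), nb1.size)
    (m1i, m2i, v1i, v2i, ci), n_i = moments[INTERVENTION]
    (m1c, m2c, v1c, v2c, cc), n_c = moments[CONTROL]
    b1s = m1i - m1c
    b2s = m2i - m2c
    v1s = v1i / n_i + v1c / n_c
    v2s = v2i / n_i + v2c / n_c
    covs = ci / n_i + cc / n_c
    denom = (b2s - b1s) ** 2 + v1s + v2s
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_c_star = np.where(denom > 0, 2 * covs / np.where(denom > 0, denom, 1.0), 1.0)
    rho_c_star = np.clip(rho_c_star, -_CLIP, _CLIP)
    z_star = np.arctanh(rho_c_star)
    se_z = float(z_star.std(ddof=1))

    degenerate = se_z == 0 and rho_c >= _CLIP
    z_hat = float(np.arctanh(np.clip(rho_c, -_CLIP, _CLIP)))
    zcrit = norm.ppf(1 - alpha / 2)
    ci_low = float(np.tanh(z_hat - zcrit * se_z))
    ci_high = float(np.tanh(z_hat + zcrit * se_z))
    if degenerate:
        rho_c = 1.0
        ci_low = ci_high = 1.0

    if rho_c0_fixed is not None:
        rho_c0 = float(rho_c0_fixed)
    else:
        if x_loss is None:
            raise ValidationError("provide x_loss or rho_c0_fixed")
        rho_c0 = ccc_threshold(rho, c_b, x_loss)

    z_rc0 = float(np.arctanh(np.clip(rho_c0, -_CLIP, _CLIP)))
    if se_z == 0:
        p_one = 0.0 if z_hat > z_rc0 else (0.5 if z_hat == z_rc0 else 1.0)
    else:
        p_one = float(norm.sf((z_hat - z_rc0) / se_z))

    return ConcordanceResult(
        lam=lam,
        rho_c=rho_c,
        rho=rho,
        c_b=c_b,
        z_rho_c=z_hat,
        se_z=se_z,
        ci_low=ci_low,
        ci_high=ci_high,
        rho_c0=rho_c0,
        p_one_sided=p_one,
        n_boot=n_boot,
        seed=seed,
        degenerate=degenerate,
    )


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-row sub-seeds (two per λ: miscoverage, CCC)."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(2 * n, dtype=np.uint32).astype(np.int64) % (2**31)


def default_lambda_grid(lo: float = 0.0, hi: float = 500_000.0, steps: int = 101) -> np.ndarray:
    return np.linspace(lo, hi, steps)


def agreement_curve(
    data: PairedTrialData,
    lambda_grid: Sequence[float] | None = None,
    referent: int = 1,
    n_boot: int = 1000,
    alpha: float = 0.05,
    x_loss: float | None = 0.05,
    rho_c0_fixed: float | None = None,
    seed: int = 0,
) -> AgreementCurve:
    """All three agreement statistics swept over a threshold grid.

    Each row reproduces exactly what the standalone operations return at
    that λ with the row's recorded sub-seeds (``misc_seed``, ``ccc_seed``),
    so individual rows can be audited in isolation.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    grid = np.asarray([_check_lambda(l) for l in lambda_grid], dtype=float)
    if grid.size == 0:
        raise ValidationError("lambda grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("lambda grid must be strictly increasing")
    test = 2 if referent == 1 else 1
    seeds = _sub_seeds(seed, grid.size)
    rows = []
    for i, lam in enumerate(grid):
        misc_seed = int(seeds[2 * i])
        ccc_seed = int(seeds[2 * i + 1])
        diff = inb_difference(data, lam)
        misc = miscoverage(data, referent, test, lam, n_boot, alpha, misc_seed)
        conc = concordance(
            data, lam, n_boot, ccc_seed, x_loss=x_loss,
            rho_c0_fixed=rho_c0_fixed, alpha=alpha,
        )
        rows.append(
            {
                "lambda": lam,
                "beta_1": diff.beta_1,
                "se_1": diff.se_1,
                "beta_2": diff.beta_2,
                "se_2": diff.se_2,
                "omega": diff.omega,
                "se_omega": diff.se_omega,
                "z": diff.z,
                "p_two_sided": diff.p_two_sided,
                "miscoverage": misc.miscoverage,
                "rho_c": conc.rho_c,
                "ci_low": conc.ci_low,
                "ci_high": conc.ci_high,
                "rho": conc.rho,
                "c_b": conc.c_b,
                "rho_c0": conc.rho_c0,
                "p_ccc": conc.p_one_sided,
                "misc_seed": misc_seed,
                "ccc_seed": ccc_seed,
            }
        )
    return AgreementCurve(frame=pd.DataFrame(rows))
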