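"""Sea-urchin embryo test (SET) toxicity statistics.

The SET bioassay exposes fertilized *Paracentrotus lividus* eggs to
leachate dilutions for 48 h; the endpoint is larval size increase
(pluteus length minus mean egg size).  This module implements the full
endpoint chain:

* control acceptability (fertilization > 95%, control increase > 253 um),
* control-corrected (normalized) responses per vial,
* a probit concentration-response fit of growth inhibition on log10
  dilution, I(d) = Phi(b0 + b1 log10 d),
* ECx point estimates with delta-method confidence intervals on the
  log10 scale, flagged "n.c." (not calculable) when the estimate exceeds
  the undiluted leachate (d > 1),
* toxic units TU = 1/EC20,
* NOEC/LOEC from many-to-one comparisons against the control (Dunnett's
  test, or Dunnett's T3 under heteroscedasticity), gated by Levene's
  test, with Shapiro-Wilk normality reported alongside.

Dilutions are volume fractions in (0, 1]; "concentration" increases with
the fraction, so the undiluted leachate (d = 1) is the highest tested
concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "CONTROL",
    "Vial",
    "BioassayDataset",
    "ProbitFit",
    "ECx",
    "AcceptabilityResult",
    "ManyToOneResult",
    "NoecLoec",
    "ToxicityEndpoints",
    "compute_size_increase",
    "check_control_acceptability",
    "normalize_to_control",
    "fit_probit",
    "estimate_ecx",
    "toxic_units",
    "dunnett_test",
    "dunnett_t3_test",
    "derive_noec_loec",
    "derive_endpoints",
    "endpoints_table",
    "read_bioassays",
]

#: Treatment marker for the artificial-seawater control group.
CONTROL = "control"

#: Control-acceptability thresholds (strict inequalities).
MIN_FERTILIZATION_PCT = 95.0
MIN_CONTROL_INCREASE_UM = 253.0

NOT_CALCULABLE = "n.c."


@dataclass
class Vial:
    """One replicate vial: a treatment level and its larval lengths (um)."""

    vial_id: str
    treatment: float | str  # dilution fraction in (0, 1] or CONTROL
    lengths_um: np.ndarray

    def __post_init__(self) -> None:
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.lengths_um.size == 0:
            raise ValueError(f"vial {self.vial_id}: no larval lengths")
        if np.any(self.lengths_um <= 0):
            raise ValueError(f"vial {self.vial_id}: lengths must be positive")
        if self.treatment != CONTROL:
            d = float(self.treatment)
            if not (0.0 < d <= 1.0):
                raise ValueError(
                    f"vial {self.vial_id}: dilution {d} outside (0, 1]"
                )
            self.treatment = d

    @property
    def is_control(self) -> bool:
        return self.treatment == CONTROL


@dataclass
class BioassayDataset:
    """A complete assay: control vials plus one or more dilution levels."""

    sample_id: str
    egg_mean_um: float
    fertilization_pct: float
    vials: list[Vial]

    def __post_init__(self) -> None:
        if self.egg_mean_um <= 0:
            raise ValueError("egg_mean_um must be positive")
        if not any(v.is_control for v in self.vials):
            raise ValueError(f"{self.sample_id}: no control vials present")

    @property
    def control_vials(self) -> list[Vial]:
        return [v for v in self.vials if v.is_control]

    @property
    def treatment_vials(self) -> list[Vial]:
        return [v for v in self.vials if not v.is_control]

    @property
    def dilutions(self) -> list[float]:
        """Distinct tested dilutions, ascending (most dilute first)."""
        return sorted({float(v.treatment) for v in self.treatment_vials})


@dataclass
class ProbitFit:
    """Probit inhibition fit I(d) = Phi(b0 + b1 log10 d) on per-vial means."""

    b0: float
    b1: float
    covariance: np.ndarray
    df: int
    converged: bool


@dataclass
class ECx:
    """Effect concentration at level x% with a 95% CI, as a dilution fraction."""

    x: float
    estimate: float
    ci_low: float
    ci_high: float
    calculable: bool


@dataclass
class AcceptabilityResult:
    passed: bool
    reasons: list[str]
    fertilization_pct: float
    control_mean_increase_um: float


@dataclass
class ManyToOneResult:
    """Per-treatment adjusted p-values for comparisons against the control."""

    method: str  # "dunnett" or "dunnett_t3"
    treatments: list[float]
    statistic: np.ndarray
    pvalue: np.ndarray
    seed: int | None = None


@dataclass
class NoecLoec:
    noec: float | None
    loec: float | None
    noec_label: str
    loec_label: str
    method: str
    shapiro_p: float
    levene_p: float
    anova_p: float
    pvalues: dict[float, float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class ToxicityEndpoints:
    """One assay's endpoint row, mirroring a toxicity summary table."""

    sample_id: str
    acceptability: AcceptabilityResult
    ec50: ECx | None = None
    ec20: ECx | None = None
    tu: float | None = None
    noec_loec: NoecLoec | None = None


def compute_size_increase(v: Vial, egg_mean_um: float) -> np.ndarray:
    """Per-larva size increase: measured length minus mean egg size (um).

    Negative increases (larva shorter than the mean egg) are retained but
    flagged with a warning — they indicate severe inhibition or a
    measurement problem.
    """
    if egg_mean_um <= 0:
        raise ValueError("egg_mean_um must be positive")
    inc = v.lengths_um - egg_mean_um
    if np.any(inc < 0):
        warnings.warn(
            f"vial {v.vial_id}: {int(np.sum(inc < 0))} larvae shorter than "
            "the mean egg size (negative size increase retained)",
            stacklevel=2,
        )
    return inc


def _control_mean_increase(ds: BioassayDataset) -> float:
    """Mean of per-vial mean control increases (each vial weighted equally)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        means = [
            float(np.mean(compute_size_increase(v, ds.egg_mean_um)))
            for v in ds.control_vials
        ]
    return float(np.mean(means))


def check_control_acceptability(ds: BioassayDataset) -> AcceptabilityResult:
    """Assay acceptability: fertilization > 95% and control increase > 253 um.

    Both thresholds are strict, so an assay at exactly the threshold fails.
    """
    if ds.fertilization_pct is None or np.isnan(ds.fertilization_pct):
        raise ValueError(f"{ds.sample_id}: fertilization_pct missing")
    ctrl = _control_mean_increase(ds)
    reasons = []
    if not ds.fertilization_pct > MIN_FERTILIZATION_PCT:
        reasons.append(
            f"fertilization {ds.fertilization_pct:g}% <= {MIN_FERTILIZATION_PCT:g}%"
        )
    if not ctrl > MIN_CONTROL_INCREASE_UM:
        reasons.append(
            f"control mean size increase {ctrl:.1f} um <= "
            f"{MIN_CONTROL_INCREASE_UM:g} um"
        )
    return AcceptabilityResult(
        passed=not reasons,
        reasons=reasons,
        fertilization_pct=float(ds.fertilization_pct),
        control_mean_increase_um=ctrl,
    )


def normalize_to_control(ds: BioassayDataset) -> pd.DataFrame:
    """Per-vial normalized responses r = vial mean increase / control mean.

    Control vials average to r = 1 by construction.  Values above 1
    (treatments outgrowing the control) are retained, not clipped.
    Columns: treatment, vial_id, n_larvae, mean_increase_um, r.
    """
    ctrl = _control_mean_increase(ds)
    if ctrl <= 0:
        raise ValueError(
            f"{ds.sample_id}: control mean size increase {ctrl:.1f} um is "
            "not positive; normalized responses undefined"
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in ds.vials:
            m = float(np.mean(compute_size_increase(v, ds.egg_mean_um)))
            rows.append(
                dict(
                    treatment=v.treatment,
                    vial_id=v.vial_id,
                    n_larvae=int(v.lengths_um.size),
                    mean_increase_um=m,
                    r=m / ctrl,
                )
            )
    return pd.DataFrame(rows)


def _probit_model(x: np.ndarray, b0: float, b1: float) -> np.ndarray:
    return stats.norm.cdf(b0 + b1 * x)


def fit_probit(ds: BioassayDataset) -> ProbitFit:
    """Weighted probit fit of growth inhibition on log10 dilution.

    Inhibition I = 1 - r per treatment vial is regressed on
    x = log10(dilution) via nonlinear least squares on
    I = Phi(b0 + b1 x), weighting each vial by its larva count.  The
    parameter covariance is scaled by the residual variance, so CIs
    downstream use t critical values at df = n_vials - 2.

    Responses indistinguishable from the control (no dose signal) give
    ``converged=False`` rather than raising; endpoints then report "n.c.".
    """
    norm_df = normalize_to_control(ds)
    treat = norm_df[norm_df["treatment"] != CONTROL]
    dil = treat["treatment"].astype(float).to_numpy()
    if len(np.unique(dil)) < 2:
        raise ValueError(
            f"{ds.sample_id}: probit fit needs >= 2 distinct dilutions"
        )
    x = np.log10(dil)
    inhibition = 1.0 - treat["r"].to_numpy(dtype=float)
    w = treat["n_larvae"].to_numpy(dtype=float)
    df = len(x) - 2

    if np.ptp(inhibition) < 1e-9:
        return ProbitFit(np.nan, np.nan, np.full((2, 2), np.nan), df, False)

    # Initial values from a linear probit regression on clipped inhibition.
    z = stats.norm.ppf(np.clip(inhibition, 1e-4, 1 - 1e-4))
    try:
        slope, intercept = np.polyfit(x, z, 1, w=np.sqrt(w))
        p0 = (float(intercept), float(slope))
    except Exception:
        p0 = (0.0, 1.0)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _probit_model,
                x,
                inhibition,
                p0=p0,
                sigma=1.0 / np.sqrt(w),
                absolute_sigma=False,
                maxfev=20000,
            )
    except RuntimeError:
        return ProbitFit(np.nan, np.nan, np.full((2, 2), np.nan), df, False)

    # Gauss-Newton covariance s^2 (J' W J)^-1 with the analytic Jacobian;
    # well defined even at an exact (zero-residual) fit, where it collapses
    # to the zero matrix.  A singular J' W J means the slope is not
    # identifiable from the data and the fit is reported as non-converged.
    converged = bool(np.all(np.isfinite(popt)))
    pcov = np.full((2, 2), np.nan)
    if converged:
        eta_hat = popt[0] + popt[1] * x
        phi_hat = stats.norm.pdf(eta_hat)
        jac_hat = np.column_stack([phi_hat, phi_hat * x])
        jtwj = (jac_hat.T * w) @ jac_hat
        resid = inhibition - _probit_model(x, *popt)
        s2 = float(np.sum(w * resid**2)) / max(df, 1)
        try:
            pcov = s2 * np.linalg.inv(jtwj)
        except np.linalg.LinAlgError:
            converged = False
    converged = converged and bool(np.all(np.isfinite(pcov)))

    if converged:
        # Every response is normalized by the same estimated control mean,
        # so its sampling error is a common, correlated disturbance that the
        # per-vial residual scatter cannot register: if the control mean is
        # off by relative error eps, every inhibition shifts by ~(1 - I)·eps.
        # Propagate that through the weighted-least-squares sensitivity as a
        # rank-1 addition to the parameter covariance.
        ctrl_means = norm_df[norm_df["treatment"] == CONTROL][
            "mean_increase_um"
        ].to_numpy(dtype=float)
        if ctrl_means.size >= 2 and np.mean(ctrl_means) > 0:
            var_eps = (
                np.var(ctrl_means, ddof=1) / ctrl_means.size / np.mean(ctrl_means) ** 2
            )
            eta = popt[0] + popt[1] * x
            phi = stats.norm.pdf(eta)
            jac = np.column_stack([phi, phi * x])
            jtw = jac.T * w
            try:
                sens = np.linalg.solve(jtw @ jac, jtw)  # d(b0,b1)/d(inhibition)
                shift = sens @ (1.0 - _probit_model(x, *popt))
                pcov = pcov + var_eps * np.outer(shift, shift)
            except np.linalg.LinAlgError:
                pass

    return ProbitFit(
        b0=float(popt[0]),
        b1=float(popt[1]),
        covariance=pcov,
        df=df,
        converged=converged,
    )


def estimate_ecx(fit: ProbitFit, x: float = 50.0, conf: float = 0.95) -> ECx:
    """ECx from a probit fit: log10 ECx = (Phi^-1(x/100) - b0) / b1.

    The 95% CI is the delta method on log10 ECx with the t quantile at
    the fit's residual df, back-transformed.  ``calculable`` is False for
    a non-converged fit, a non-positive slope, or an estimate above the
    undiluted leachate (dilution fraction > 1) — the "n.c." semantics of
    toxicity summary tables.
    """
    if not (0.0 < x < 100.0):
        raise ValueError("effect level x must be in (0, 100)")
    if not fit.converged or not np.isfinite(fit.b1) or fit.b1 <= 0:
        return ECx(x=x, estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                   calculable=False)
    z = stats.norm.ppf(x / 100.0)
    g = (z - fit.b0) / fit.b1  # log10 ECx
    grad = np.array([-1.0 / fit.b1, -(z - fit.b0) / fit.b1**2])
    var = float(grad @ fit.covariance @ grad)
    se = np.sqrt(max(var, 0.0))
    tcrit = stats.t.ppf(0.5 + conf / 2.0, max(fit.df, 1))
    lo, hi = 10.0 ** (g - tcrit * se), 10.0 ** (g + tcrit * se)
    est = 10.0**g
    return ECx(
        x=x,
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        calculable=bool(est <= 1.0),
    )


def toxic_units(ec20: ECx) -> float | None:
    """Toxic units TU = 1/EC20; absent when EC20 is not calculable."""
    if not ec20.calculable:
        return None
    return 1.0 / ec20.estimate


def dunnett_test(
    groups: Sequence[np.ndarray],
    control: np.ndarray,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> ManyToOneResult:
    """Dunnett's many-to-one comparisons against a shared control.

    Pooled-variance t statistics per treatment; two-sided p-values
    adjusted under the multivariate t distribution of the simultaneous
    comparisons (correlations induced by the shared control).  With a
    single treatment this reduces to the ordinary pooled t-test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = np.asarray(control, dtype=float)
    if len(groups) < 1:
        raise ValueError("at least one treatment group required")
    for g in [*groups, control]:
        if g.size < 2:
            raise ValueError("each group needs >= 2 replicates")
    rng = np.random.default_rng(seed) if seed is not None else None
    res = stats.dunnett(*groups, control=control, alternative="two-sided",
                        random_state=rng)
    return ManyToOneResult(
        method="dunnett",
        treatments=list(range(len(groups))),
        statistic=np.atleast_1d(res.statistic),
        pvalue=np.clip(np.atleast_1d(res.pvalue), 0.0, 1.0),
        seed=seed,
    )


def dunnett_t3_test(
    groups: Sequence[np.ndarray],
    control: np.ndarray,
    alpha: float = 0.05,
) -> ManyToOneResult:
    """Dunnett's T3 comparisons for unequal variances.

    Welch-type statistics with Satterthwaite df per comparison; the
    familywise adjustment uses the studentized maximum modulus over the k
    comparisons, p_adj = 1 - (2 F_t(|t|; df) - 1)^k.  With one treatment
    this is exactly the two-sided Welch t-test; with several it is
    conservative-to-nominal under heteroscedasticity.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = np.asarray(control, dtype=float)
    if len(groups) < 1:
        raise ValueError("at least one treatment group required")
    for g in [*groups, control]:
        if g.size < 2:
            raise ValueError("each group needs >= 2 replicates")
    k = len(groups)
    n0, m0, v0 = control.size, control.mean(), control.var(ddof=1)
    tstats, pvals = [], []
    for g in groups:
        ni, mi, vi = g.size, g.mean(), g.var(ddof=1)
        se2 = vi / ni + v0 / n0
        if se2 == 0:
            tstats.append(0.0)
            pvals.append(1.0)
            continue
        t = (mi - m0) / np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (v0 / n0) ** 2 / (n0 - 1))
        inner = 2.0 * stats.t.cdf(abs(t), df) - 1.0
        pvals.append(1.0 - inner**k)
        tstats.append(float(t))
    return ManyToOneResult(
        method="dunnett_t3",
        treatments=list(range(k)),
        statistic=np.asarray(tstats),
        pvalue=np.clip(np.asarray(pvals), 0.0, 1.0),
    )


def _format_dilution(d: float) -> str:
    return f"{d:g}"


def derive_noec_loec(
    ds: BioassayDataset,
    alpha: float = 0.05,
    gating: str = "standard",
    seed: int | None = 0,
) -> NoecLoec:
    """NOEC/LOEC from many-to-one tests on raw per-vial size increases.

    Pipeline: Shapiro-Wilk on one-way ANOVA residuals (reported, not
    blocking), Levene's test across groups, one-way ANOVA, then Dunnett's
    test or Dunnett's T3.  Gating:

    * ``"standard"`` (default): Levene p < alpha (heteroscedastic) -> T3,
      otherwise Dunnett — the textbook assignment of T3 to unequal
      variances.
    * ``"literal"``: the inverse assignment (Dunnett when Levene is
      significant).

    LOEC is the least concentrated (smallest-fraction) treatment with
    adjusted p < alpha; NOEC is the greatest tested concentration below
    it.  With no significant treatment, NOEC is the highest tested
    concentration and LOEC is "n.c."; with every treatment significant,
    NOEC reports as below the lowest tested concentration.  A significant
    dose below a non-significant one triggers a non-monotonicity warning.
    """
    if gating not in ("standard", "literal"):
        raise ValueError(f"unknown gating {gating!r}")
    norm_df = normalize_to_control(ds)
    ctrl = norm_df[norm_df["treatment"] == CONTROL]["mean_increase_um"].to_numpy()
    dilutions = ds.dilutions
    if not dilutions:
        raise ValueError(f"{ds.sample_id}: no treatment groups")
    group_vals = []
    for d in dilutions:
        vals = norm_df[norm_df["treatment"] == d]["mean_increase_um"].to_numpy()
        if vals.size < 2:
            raise ValueError(
                f"{ds.sample_id}: dilution {d:g} has fewer than 2 replicate vials"
            )
        group_vals.append(vals)
    if ctrl.size < 2:
        raise ValueError(f"{ds.sample_id}: fewer than 2 control vials")

    all_groups = [ctrl, *group_vals]
    resid = np.concatenate([g - g.mean() for g in all_groups])
    shapiro_p = float(stats.shapiro(resid).pvalue)
    levene_p = float(stats.levene(*all_groups, center="mean").pvalue)
    anova_p = float(stats.f_oneway(*all_groups).pvalue)

    heteroscedastic = levene_p < alpha
    use_t3 = heteroscedastic if gating == "standard" else not heteroscedastic
    if use_t3:
        res = dunnett_t3_test(group_vals, ctrl, alpha=alpha)
    else:
        res = dunnett_test(group_vals, ctrl, alpha=alpha, seed=seed)
    pvalues = {d: float(p) for d, p in zip(dilutions, res.pvalue)}

    warns = []
    if shapiro_p < alpha:
        warns.append(
            f"Shapiro-Wilk p={shapiro_p:.3g} < {alpha:g}: residuals depart "
            "from normality (reported, not acted on)"
        )
    significant = [d for d in dilutions if pvalues[d] < alpha]
    # Non-monotonic pattern: a significant dose below a non-significant one.
    if significant:
        loec = min(significant)
        above_loec = [d for d in dilutions if d > loec]
        if any(pvalues[d] >= alpha for d in above_loec):
            warns.append(
                "non-monotonic significance pattern: a dose above the LOEC "
                "is not significant"
            )
        below = [d for d in dilutions if d < loec]
        if below:
            noec = max(below)
            noec_label = _format_dilution(noec)
        else:
            noec = None
            noec_label = f"< {_format_dilution(min(dilutions))}"
        loec_label = _format_dilution(loec)
    else:
        loec = None
        loec_label = NOT_CALCULABLE
        noec = max(dilutions)
        noec_label = _format_dilution(noec)

    return NoecLoec(
        noec=noec,
        loec=loec,
        noec_label=noec_label,
        loec_label=loec_label,
        method=res.method,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        anova_p=anova_p,
        pvalues=pvalues,
        warnings=warns,
    )


def derive_endpoints(
    ds: BioassayDataset,
    alpha: float = 0.05,
    gating: str = "standard",
    seed: int | None = 0,
    enforce_acceptability: bool = True,
) -> ToxicityEndpoints:
    """Full endpoint chain for one assay.

    An assay failing the control acceptability criteria is withheld: the
    result carries only the acceptability record and its reasons.
    """
    acc = check_control_acceptability(ds)
    out = ToxicityEndpoints(sample_id=ds.sample_id, acceptability=acc)
    if enforce_acceptability and not acc.passed:
        return out
    fit = fit_probit(ds)
    out.ec50 = estimate_ecx(fit, 50.0)
    out.ec20 = estimate_ecx(fit, 20.0)
    out.tu = toxic_units(out.ec20)
    out.noec_loec = derive_noec_loec(ds, alpha=alpha, gating=gating, seed=seed)
    return out


def _fmt_ecx(e: ECx | None) -> str:
    if e is None or not e.calculable:
        return NOT_CALCULABLE
    return f"{e.estimate:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f})"


def endpoints_table(results: Sequence[ToxicityEndpoints]) -> pd.DataFrame:
    """Summary table with NOEC, LOEC, EC20 (CI), EC50 (CI) and TU per assay.

    Non-calculable entries use the literal string "n.c."; rejected assays
    are marked with their acceptability reasons.
    """
    rows = []
    for r in results:
        if not r.acceptability.passed:
            rows.append(
                dict(
                    sample_id=r.sample_id,
                    status="assay rejected: " + "; ".join(r.acceptability.reasons),
                    noec="", loec="", ec20="", ec50="", tu="",
                )
            )
            continue
        nl = r.noec_loec
        rows.append(
            dict(
                sample_id=r.sample_id,
                status="ok",
                noec=nl.noec_label if nl else NOT_CALCULABLE,
                loec=nl.loec_label if nl else NOT_CALCULABLE,
                ec20=_fmt_ecx(r.ec20),
                ec50=_fmt_ecx(r.ec50),
                tu=f"{r.tu:.2f}" if r.tu is not None else NOT_CALCULABLE,
            )
        )
    return pd.DataFrame(rows)


def read_bioassays(data_path, metadata_path) -> list[BioassayDataset]:
    """Read assays from a long-format CSV plus a per-sample metadata CSV.

    ``data_path`` columns: sample_id, treatment ("control" or a dilution
    fraction), vial_id, larva_id, length_um.  ``metadata_path`` columns:
    sample_id, egg_mean_um, fertilization_pct.
    """
    df = pd.read_csv(data_path)
    required = {"sample_id", "treatment", "vial_id", "larva_id", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bioassay table missing columns: {sorted(missing)}")
    meta = pd.read_csv(metadata_path).set_index("sample_id")
    datasets = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        if sample_id not in meta.index:
            raise ValueError(f"no metadata row for sample {sample_id!r}")
        vials = []
        for (treatment, vial_id), vial_rows in sub.groupby(
            ["treatment", "vial_id"], sort=True
        ):
            t = CONTROL if str(treatment) == CONTROL else float(treatment)
            vials.append(
                Vial(
                    vial_id=str(vial_id),
                    treatment=t,
                    lengths_um=vial_rows["length_um"].to_numpy(dtype=float),
                )
            )
        datasets.append(
            BioassayDataset(
                sample_id=str(sample_id),
                egg_mean_um=float(meta.loc[sample_id, "egg_mean_um"]),
                fertilization_pct=float(meta.loc[sample_id, "fertilization_pct"]),
                vials=vials,
            )
        )
    return datasets
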