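"""Two-sample univariable and multivariable Mendelian randomisation.

Instruments are SNPs robustly associated with the exposure (p < 5e-8,
optionally LD-pruned at r^2 <= 0.001 within 10,000 kb). After harmonising
exposure and outcome to a common effect allele (palindromic A/T and G/C SNPs
dropped unless allele frequencies resolve their orientation), the causal
effect of the exposure on the outcome is estimated by:

* inverse-variance weighting (IVW) of per-SNP Wald ratios — equivalent to a
  weighted regression of beta_y on beta_x through the origin with weights
  1/se_y^2; a multiplicative random-effects model (SE inflated by
  max(1, sqrt(Q/(J-1)))) is used when Cochran's Q is significant;
* MR-Egger regression (slope = causal effect, intercept = average directional
  pleiotropy);
* the weighted median and weighted mode of the per-SNP ratio estimates
  (robust to up to 50% / a plurality of invalid instruments);
* MR-PRESSO global, per-SNP outlier and distortion tests based on the
  leave-one-out residual sum of squares compared with parametric simulations
  under the no-pleiotropy model;
* multivariable IVW (weighted multiple regression of beta_y on the matrix of
  exposure betas, no intercept), giving each exposure's direct effect.

Estimates are on the scale of the outcome betas; for binary outcomes these
are log-odds, and every fit also carries OR = exp(estimate) with the
exponentiated confidence interval. Per-SNP instrument strength is
F_j = (beta_x/se_x)^2, with a weak-instrument warning when the mean F < 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crosstrait import clump

__all__ = [
    "HarmonisedInstrument",
    "MrFit",
    "PressoResult",
    "select_instruments",
    "harmonise",
    "instruments_frame",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
    "mvmr_ivw",
    "f_statistic",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PALINDROMES = ({"A", "T"}, {"G", "C"})


@dataclass
class HarmonisedInstrument:
    snp: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    action: str = "kept"  # kept | flipped | dropped_palindromic | dropped_missing


@dataclass
class MrFit:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    model: str = "fixed"
    q: float = float("nan")
    q_df: int = 0
    q_p: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_p: float = float("nan")
    exposure: str = ""

    @property
    def or_estimate(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class PressoResult:
    global_rss_p: float
    outlier_snps: list[str]
    outlier_p_by_snp: dict[str, float]  # Bonferroni-adjusted empirical p
    distortion_p: float
    estimate_before: float
    estimate_after: float
    n_sim: int = 0


# ---------------------------------------------------------------------------
# instrument selection and harmonisation


def select_instruments(
    exposure: pd.DataFrame,
    p_max: float = 5e-8,
    r2_lookup: Mapping | None = None,
    r2: float = 0.001,
    window_kb: int = 10_000,
) -> pd.DataFrame:
    """Genome-wide-significant, LD-pruned instruments for one exposure.

    Keeps SNPs with p < ``p_max`` (strict) and, when an r^2 lookup is
    supplied, clumps them at r^2 <= ``r2`` within ``window_kb``. Without a
    lookup only the p-value filter applies (warned).
    """
    sig = exposure[exposure["p"] < p_max]
    if sig.empty:
        raise ValueError("no instruments: no SNP passes the significance threshold")
    if r2_lookup is None:
        warnings.warn("no r2 lookup supplied: instruments are p-filtered only")
        return sig.reset_index(drop=True)
    out = clump(sig, r2_lookup, p1=p_max, p2=1.0, r2=r2, window_kb=window_kb)
    return out.reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMES


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    drop_palindromic: bool = True,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonisedInstrument]:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Direct allele match is kept; swapped alleles flip the sign of beta_y;
    strand flips (complementary alleles) are resolved the same way.
    Palindromic SNPs are dropped when ``drop_palindromic`` unless both allele
    frequencies lie outside [0.5 - w, 0.5 + w], in which case the orientation
    is inferred by frequency matching. Unresolvable allele mismatches are
    dropped. The returned list covers every joined SNP with its action.
    """
    ex = exposure.set_index("snp")
    out = outcome.set_index("snp")
    common = [s for s in ex.index if s in out.index]
    if not common:
        raise ValueError("exposure and outcome share no SNPs")
    results: list[HarmonisedInstrument] = []
    w = palindrome_eaf_window
    for snp in common:
        e, o = ex.loc[snp], out.loc[snp]
        a1, a2 = str(e["a1"]).upper(), str(e["a2"]).upper()
        b1, b2 = str(o["a1"]).upper(), str(o["a2"]).upper()
        eaf_x = float(e["eaf"]) if pd.notna(e.get("eaf", np.nan)) else None
        eaf_y = float(o["eaf"]) if pd.notna(o.get("eaf", np.nan)) else None
        inst = HarmonisedInstrument(
            snp=snp,
            beta_x=float(e["beta"]),
            se_x=float(e["se"]),
            beta_y=float(o["beta"]),
            se_y=float(o["se"]),
            eaf_x=eaf_x,
            eaf_y=eaf_y,
        )
        comp = {a1, a2} <= set(_COMPLEMENT)
        c1 = _COMPLEMENT.get(b1, "?")
        c2 = _COMPLEMENT.get(b2, "?")
        if (b1, b2) == (a1, a2):
            action = "kept"
        elif (b1, b2) == (a2, a1):
            action = "flipped"
        elif comp and (c1, c2) == (a1, a2):
            action = "kept"
        elif comp and (c1, c2) == (a2, a1):
            action = "flipped"
        else:
            inst.action = "dropped_missing"
            results.append(inst)
            continue
        if action == "flipped":
            inst.beta_y = -inst.beta_y
            if inst.eaf_y is not None:
                inst.eaf_y = 1.0 - inst.eaf_y
        inst.action = action
        if _is_palindromic(a1, a2):
            inferable = (
                inst.eaf_x is not None
                and inst.eaf_y is not None
                and abs(inst.eaf_x - 0.5) > w
                and abs(inst.eaf_y - 0.5) > w
            )
            if inferable:
                if (inst.eaf_x - 0.5) * (inst.eaf_y - 0.5) < 0:
                    # frequencies disagree: the nominal alignment was a strand
                    # artefact; flip the outcome effect
                    inst.beta_y = -inst.beta_y
                    inst.eaf_y = 1.0 - inst.eaf_y
                    inst.action = "flipped"
            elif drop_palindromic:
                inst.action = "dropped_palindromic"
        results.append(inst)
    return results


def instruments_frame(instruments) -> pd.DataFrame:
    """Coerce harmonised instruments (list or frame) to a kept-rows DataFrame."""
    if isinstance(instruments, pd.DataFrame):
        df = instruments.copy()
        if "action" in df.columns:
            df = df[df["action"].isin(["kept", "flipped"])]
    else:
        rows = [
            (i.snp, i.beta_x, i.se_x, i.beta_y, i.se_y)
            for i in instruments
            if i.action in ("kept", "flipped")
        ]
        df = pd.DataFrame(rows, columns=["snp", "beta_x", "se_x", "beta_y", "se_y"])
    if "snp" not in df.columns:
        df = df.copy()
        df["snp"] = [f"snp{i}" for i in range(len(df))]
    return df.reset_index(drop=True)


def _arrays(instruments) -> tuple[np.ndarray, ...]:
    df = instruments_frame(instruments)
    return (
        df["beta_x"].to_numpy(float),
        df["se_x"].to_numpy(float),
        df["beta_y"].to_numpy(float),
        df["se_y"].to_numpy(float),
        df["snp"].to_numpy(str),
    )


# ---------------------------------------------------------------------------
# estimators


def _normal_fit(method, est, se, j, **kw) -> MrFit:
    z = est / se if se > 0 else np.inf
    p = 2.0 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(0.975) * se
    return MrFit(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - half),
        ci_high=float(est + half),
        p=float(p),
        n_snps=int(j),
        **kw,
    )


def ivw(instruments, random_effects: str = "auto") -> MrFit:
    """Inverse-variance-weighted estimate of the causal effect.

    Fixed-effect by default; with ``random_effects='auto'`` (the default
    rule) the SE is inflated multiplicatively by max(1, sqrt(Q/(J-1))) when
    Cochran's Q has p < 0.05. A single instrument degrades to the Wald ratio
    with a warning.
    """
    bx, _, by, sy, _ = _arrays(instruments)
    j = len(bx)
    if j == 0:
        raise ValueError("no instruments")
    if np.all(bx == 0):
        raise ValueError("all exposure effects are zero")
    if j == 1:
        warnings.warn("single instrument: Wald ratio estimate")
        est = by[0] / bx[0]
        se = sy[0] / abs(bx[0])
        return _normal_fit("ivw_fe", est, se, 1, model="fixed")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    est = float(np.sum(w * bx * by)) / sxx
    se_fe = sxx**-0.5
    q, q_df, q_p = cochran_q(instruments, est)
    model, se = "fixed", se_fe
    use_re = (random_effects == "always") or (random_effects == "auto" and q_p < 0.05)
    if use_re:
        model, se = "random", se_fe * max(1.0, np.sqrt(q / (j - 1)))
    return _normal_fit(
        "ivw_re" if model == "random" else "ivw_fe",
        est, se, j, model=model, q=q, q_df=q_df, q_p=q_p,
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares; returns (coef, cov_unscaled, rss)."""
    xw = x * w[:, None]
    xtx = x.T @ xw
    coef = np.linalg.solve(xtx, xw.T @ y)
    resid = y - x @ coef
    rss = float(np.sum(w * resid**2))
    return coef, np.linalg.inv(xtx), rss


def egger(instruments) -> MrFit:
    """MR-Egger regression: slope = causal effect, intercept = mean pleiotropy.

    Weighted regression of beta_y on beta_x with intercept, weights 1/se_y^2,
    exposure effects oriented positive. Standard errors use the estimated
    residual scale RSS/(J-2) and t-distribution p-values with J-2 df.
    """
    bx, _, by, sy, _ = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    coef, cov_u, rss = _wls(x, by, w)
    scale = rss / (j - 2)
    se_vec = np.sqrt(scale * np.diag(cov_u))
    alpha, slope = coef
    se_a, se_b = se_vec
    t = stats.t(df=j - 2)
    p_slope = 2.0 * t.sf(abs(slope / se_b))
    p_alpha = 2.0 * t.sf(abs(alpha / se_a))
    half = t.ppf(0.975) * se_b
    q = rss  # Rucker's Q'
    return MrFit(
        method="egger",
        estimate=float(slope),
        se=float(se_b),
        ci_low=float(slope - half),
        ci_high=float(slope + half),
        p=float(p_slope),
        n_snps=j,
        model="fixed",
        q=float(q),
        q_df=j - 2,
        q_p=float(stats.chi2.sf(q, df=j - 2)),
        egger_intercept=float(alpha),
        egger_intercept_se=float(se_a),
        egger_intercept_p=float(p_alpha),
    )


def _ratio_weights(bx, sy) -> np.ndarray:
    return bx**2 / sy**2  # inverse variance of the Wald ratio (1st order)


def _weighted_median_est(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], w[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] < 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="left"))  # first s[k] >= 0.5
    lo, hi = k - 1, k
    return float(r[lo] + (r[hi] - r[lo]) * (0.5 - s[lo]) / (s[hi] - s[lo]))


def _drop_zero_bx(bx, sx, by, sy):
    keep = bx != 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} ratio(s) with beta_x = 0")
    return bx[keep], sx[keep], by[keep], sy[keep]


def weighted_median(instruments, n_boot: int = 1000, seed: int = 0) -> MrFit:
    """Weighted median of per-SNP Wald ratios; SE by parametric bootstrap.

    Consistent as long as at least half of the total instrument weight comes
    from valid instruments. Interpolation uses the cumulative-weight
    midpoints S_j - w_j/2.
    """
    bx, sx, by, sy, _ = _arrays(instruments)
    bx, sx, by, sy = _drop_zero_bx(bx, sx, by, sy)
    j = len(bx)
    if j < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    est = _weighted_median_est(by / bx, _ratio_weights(bx, sy))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        boots[b] = _weighted_median_est(bys[ok] / bxs[ok], _ratio_weights(bxs[ok], sy[ok]))
    se = float(boots.std(ddof=1))
    return _normal_fit("weighted_median", est, se, j)


def _weighted_mode_est(ratios: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    w = w / w.sum()
    med = _weighted_median_est(ratios, w)
    dev = np.abs(ratios - med)
    mad = _weighted_median_est(dev, w) * 1.4826
    sd = float(np.sqrt(np.sum(w * (ratios - np.sum(w * ratios)) ** 2)))
    s = min(x for x in (mad, sd) if x > 0) if max(mad, sd) > 0 else 0.0
    if s == 0.0:
        return float(ratios[0])  # all ratios identical
    h = bandwidth_factor * 0.9 * s * len(ratios) ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    instruments, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MrFit:
    """Mode of the weighted kernel-smoothed density of Wald ratios.

    Normal kernel; bandwidth 0.9 * min(weighted MAD*1.4826, weighted SD) *
    J^(-1/5), scaled by ``bandwidth_factor``. Consistent when the largest
    group of instruments sharing a ratio value is valid. SE by parametric
    bootstrap.
    """
    bx, sx, by, sy, _ = _arrays(instruments)
    bx, sx, by, sy = _drop_zero_bx(bx, sx, by, sy)
    j = len(bx)
    if j < 3:
        raise ValueError("weighted mode needs >= 3 instruments")
    est = _weighted_mode_est(by / bx, _ratio_weights(bx, sy), bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        boots[b] = _weighted_mode_est(
            bys[ok] / bxs[ok], _ratio_weights(bxs[ok], sy[ok]), bandwidth_factor
        )
    se = float(boots.std(ddof=1))
    return _normal_fit("weighted_mode", est, se, j)


def cochran_q(instruments, beta_hat: float) -> tuple[float, int, float]:
    """Cochran's Q = sum_j w_j (beta_yj - beta_hat*beta_xj)^2, df = J-1."""
    bx, _, by, sy, _ = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise ValueError("Q needs >= 2 instruments")
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - beta_hat * bx) ** 2))
    return q, j - 1, float(stats.chi2.sf(q, df=j - 1))


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over rows of (bx, by)."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    instruments, n_sim: int = 1000, outlier_p: float = 0.05, seed: int = 0,
    n_perm_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares takes each SNP's residual against
    the IVW fit of the other J-1 SNPs; its null distribution comes from
    ``n_sim`` parametric simulations drawing beta_x ~ N(beta_x, se_x^2) and
    beta_y ~ N(theta_{-j} beta_x, se_y^2) and re-fitting the leave-one-out
    slopes. Per-SNP empirical p-values are Bonferroni-adjusted across J;
    SNPs below ``outlier_p`` are outliers. The distortion test compares the
    estimate shift after outlier removal with the shifts produced by removing
    random SNP subsets of the same size.
    """
    bx, sx, by, sy, snps = _arrays(instruments)
    j = len(bx)
    if j < 4:
        raise ValueError("MR-PRESSO needs >= 4 instruments")
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, w)
    rss_obs_j = w * (by - theta_loo * bx) ** 2
    rss_obs = float(rss_obs_j.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(theta_loo * bx_s, sy, size=(n_sim, j))
    theta_s = _loo_slopes(bx_s, by_s, w)
    rss_sim_j = w * (by_s - theta_s * bx_s) ** 2
    rss_sim = rss_sim_j.sum(axis=1)

    global_p = (1.0 + float((rss_sim >= rss_obs).sum())) / (1.0 + n_sim)
    p_raw = (1.0 + (rss_sim_j >= rss_obs_j[None, :]).sum(axis=0)) / (1.0 + n_sim)
    p_adj = np.minimum(p_raw * j, 1.0)
    outliers = [snps[i] for i in range(j) if p_adj[i] < outlier_p]

    inst_df = instruments_frame(instruments)
    est_before = ivw(inst_df, random_effects="never").estimate
    if outliers:
        keep = ~np.isin(snps, outliers)
        est_after = ivw(inst_df[keep], random_effects="never").estimate
        d_obs = est_before - est_after
        k = len(outliers)
        d_perm = np.empty(n_perm_distortion)
        idx = np.arange(j)
        for b in range(n_perm_distortion):
            drop = rng.choice(idx, size=k, replace=False)
            mask = np.ones(j, bool)
            mask[drop] = False
            est_b = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
            d_perm[b] = est_before - est_b
        distortion_p = (1.0 + float((np.abs(d_perm) >= abs(d_obs)).sum())) / (
            1.0 + n_perm_distortion
        )
    else:
        est_after = est_before
        distortion_p = float("nan")
    return PressoResult(
        global_rss_p=float(global_p),
        outlier_snps=outliers,
        outlier_p_by_snp={snps[i]: float(p_adj[i]) for i in range(j)},
        distortion_p=float(distortion_p),
        estimate_before=float(est_before),
        estimate_after=float(est_after),
        n_sim=n_sim,
    )


def leave_one_out(instruments) -> pd.DataFrame:
    """IVW re-fit dropping each SNP in turn; flags sign-stability breaks."""
    df = instruments_frame(instruments)
    j = len(df)
    if j < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    full = ivw(df)
    full_excl = full.ci_low > 0 or full.ci_high < 0
    rows = []
    for i in range(j):
        fit = ivw(df.drop(df.index[i]))
        rows.append(
            {
                "dropped_snp": df["snp"].iloc[i],
                "estimate": fit.estimate,
                "se": fit.se,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "p": fit.p,
                "flips_significance": (fit.ci_low > 0 or fit.ci_high < 0) != full_excl,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multivariable MR


def mvmr_ivw(
    exposures: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    outcome: pd.DataFrame,
    instruments: Iterable[str] | None = None,
) -> list[MrFit]:
    """Multivariable IVW: direct effect of each exposure conditional on the rest.

    Weighted multiple regression of the outcome betas on the matrix of
    exposure betas (no intercept, weights 1/se_y^2) over the union of the
    exposures' instruments (or the SNP list given in ``instruments``), all
    harmonised to the outcome's effect-allele convention by sign flips on
    allele swaps. SEs use the same heterogeneity rule as univariable IVW
    (multiplicative inflation when the weighted RSS is significant on J-K df),
    so a single exposure reduces to :func:`ivw` exactly.
    """
    if not isinstance(exposures, Mapping):
        exposures = {f"exposure_{i+1}": df for i, df in enumerate(exposures)}
    names = list(exposures)
    k = len(names)
    out = outcome.set_index("snp")
    if instruments is None:
        snp_union: list[str] = []
        seen = set()
        for df in exposures.values():
            for s in df["snp"]:
                if s not in seen:
                    seen.add(s)
                    snp_union.append(s)
    else:
        snp_union = list(instruments)
    rows = []
    for snp in snp_union:
        if snp not in out.index:
            continue
        o = out.loc[snp]
        betas = []
        ok = True
        for nm in names:
            df = exposures[nm]
            hit = df[df["snp"] == snp]
            if hit.empty:
                ok = False
                break
            e = hit.iloc[0]
            a1, a2 = str(e["a1"]).upper(), str(e["a2"]).upper()
            b1, b2 = str(o["a1"]).upper(), str(o["a2"]).upper()
            if (a1, a2) == (b1, b2):
                betas.append(float(e["beta"]))
            elif (a1, a2) == (b2, b1):
                betas.append(-float(e["beta"]))
            else:
                ok = False
                break
        if ok:
            rows.append((snp, betas, float(o["beta"]), float(o["se"])))
    jn = len(rows)
    if jn <= k:
        raise ValueError("need more instruments than exposures")
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    sy = np.array([r[3] for r in rows])
    w = 1.0 / sy**2
    xw = x * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(xw) < k:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            f"{names[a]}~{names[b]}"
            for a in range(k)
            for b in range(a + 1, k)
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear exposures: {pairs or names}")
    coef, cov_u, rss = _wls(x, y, w)
    q_df = jn - k
    q_p = float(stats.chi2.sf(rss, df=q_df))
    infl = max(1.0, np.sqrt(rss / q_df)) if q_p < 0.05 else 1.0
    se_vec = np.sqrt(np.diag(cov_u)) * infl
    fits = []
    for i, nm in enumerate(names):
        fit = _normal_fit(
            "mvmr_ivw",
            coef[i],
            se_vec[i],
            jn,
            model="random" if infl > 1.0 else "fixed",
            q=float(rss),
            q_df=q_df,
            q_p=q_p,
        )
        fit.exposure = nm
        fits.append(fit)
    return fits


def f_statistic(instruments) -> tuple[np.ndarray, float]:
    """Per-SNP instrument strength F_j = (beta_x/se_x)^2 and the mean F.

    Warns when the mean F < 10 (conventional weak-instrument threshold).
    """
    df = instruments_frame(instruments)
    f = (df["beta_x"].to_numpy(float) / df["se_x"].to_numpy(float)) ** 2
    mean_f = float(f.mean()) if len(f) else float("nan")
    if len(f) and mean_f < 10:
        warnings.warn(f"weak instruments: mean F = {mean_f:.2f} < 10")
    return f, mean_f
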