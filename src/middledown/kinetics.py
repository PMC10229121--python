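"""Steady-state methyltransferase kinetics: Hill vs Michaelis-Menten.

Velocities are modelled as v(S) = Vmax * S^h / (K05^h + S^h) with
k_cat = Vmax / [E].  The Michaelis-Menten model is the h = 1 restriction of
the Hill model, so the two are compared with the extra-sum-of-squares
F-test:

    F = ((SS_MM - SS_Hill) / (df_MM - df_Hill)) / (SS_Hill / df_Hill)

with p from F(df_MM - df_Hill, df_Hill); the Hill model (positive
cooperativity when h > 1) is preferred when p < alpha.  Substrate inputs
are in nM (assay convention) while K_0.5 is reported in uM (publication
convention); the conversion happens in exactly one place here.

Datasets whose signal is indistinguishable from background are flagged
"n.d." (not determined) rather than fitted, mirroring how unmeasurable
substrates are reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ttest_two_sample
from .simulate import hill_velocity

NM_PER_UM = 1000.0


class KineticsError(ValueError):
    pass


class InsufficientDesignError(KineticsError):
    """Fewer than five distinct non-zero substrate concentrations."""


class FitFailureError(KineticsError):
    pass


@dataclass
class KineticDataset:
    """A velocity titration: substrate (nM), observed rates, enzyme (nM)."""

    substrate_nM: np.ndarray
    rate: np.ndarray
    enzyme_nM: float
    replicate: Optional[np.ndarray] = None
    background: Optional[np.ndarray] = None  # blank-reaction signals

    def __post_init__(self) -> None:
        self.substrate_nM = np.asarray(self.substrate_nM, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_nM.shape != self.rate.shape:
            raise KineticsError("substrate and rate lengths differ")
        if self.enzyme_nM <= 0:
            raise KineticsError("enzyme concentration must be > 0")
        if (self.substrate_nM < 0).any():
            raise KineticsError("substrate concentrations must be >= 0")

    @classmethod
    def from_counts(
        cls,
        substrate_nM: Sequence[float],
        counts: Sequence[float],
        enzyme_nM: float,
        specific_activity: float = 1.0,
        time_min: float = 1.0,
        **kw,
    ) -> "KineticDataset":
        """Convert raw scintillation counts to rates: counts x factor / time."""
        rate = np.asarray(counts, dtype=float) * specific_activity / time_min
        return cls(np.asarray(substrate_nM, dtype=float), rate, enzyme_nM, **kw)


@dataclass
class KineticFit:
    """Parameter estimates for one model (MM = Hill with h fixed at 1)."""

    model: str  # "MM" or "Hill"
    k_half_uM: float
    kcat_per_min: float
    hill: float
    stderr: Dict[str, Optional[float]]
    r_squared: float
    rss: float
    dof: int
    nd: bool = False
    nd_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "K_0.5_uM": "n.d." if self.nd else self.k_half_uM,
            "k_cat_per_min": "n.d." if self.nd else self.kcat_per_min,
            "h": "n.d." if self.nd else self.hill,
            "stderr": self.stderr,
            "R2": self.r_squared,
            "rss": self.rss,
            "dof": self.dof,
            "nd": self.nd,
            "nd_reason": self.nd_reason,
        }


@dataclass
class ModelComparison:
    f_stat: float
    df_num: int
    df_den: int
    p: float
    preferred: str

    def to_dict(self) -> dict:
        return {
            "F": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
            "preferred": self.preferred,
        }


def _check_design(S: np.ndarray) -> None:
    if len(set(np.round(S[S > 0], 12))) < 5:
        raise InsufficientDesignError(
            "need at least 5 distinct non-zero substrate concentrations"
        )


def _initial_guesses(S: np.ndarray, v: np.ndarray) -> Tuple[float, float]:
    """Vmax0 = max(v); K0 = S at half-max by linear interpolation."""
    vmax0 = float(np.max(v))
    order = np.argsort(S)
    Ss, vs = S[order], v[order]
    half = vmax0 / 2.0
    k0 = float(Ss[-1] / 2.0) if Ss[-1] > 0 else 1.0
    above = np.nonzero(vs >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        x0, x1, y0, y1 = Ss[i - 1], Ss[i], vs[i - 1], vs[i]
        if y1 != y0:
            k0 = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    return vmax0, max(k0, 1e-6)


def _fit_one(
    S: np.ndarray,
    v: np.ndarray,
    fix_h: bool,
    start: Optional[Dict[str, float]] = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> lmfit.minimizer.MinimizerResult:
    vmax0, k0 = _initial_guesses(S, v)
    params = lmfit.Parameters()
    params.add("vmax", value=start.get("vmax", vmax0) if start else vmax0, min=0)
    params.add("k_half", value=start.get("k_half", k0) if start else k0, min=1e-9)
    h0 = start.get("h", 1.0) if start else 1.0
    params.add("h", value=h0, min=1e-3, max=20.0, vary=not fix_h)

    def resid(p):
        return hill_velocity(S, p["k_half"].value, 1.0, p["h"].value, 1.0) * p[
            "vmax"
        ].value - v

    # jittered multistart: retry from perturbed guesses only on failure
    rng = np.random.default_rng(seed)
    for attempt in range(n_restarts + 1):
        try:
            res = lmfit.minimize(resid, params, method="leastsq")
            if res.success:
                return res
        except Exception:
            pass
        params["vmax"].value = vmax0 * rng.uniform(0.5, 2.0)
        params["k_half"].value = k0 * rng.uniform(0.3, 3.0)
        if not fix_h:
            params["h"].value = rng.uniform(0.5, 3.0)
    raise FitFailureError("nonlinear least squares did not converge")


def _summarize(
    res: lmfit.minimizer.MinimizerResult,
    v: np.ndarray,
    enzyme_nM: float,
    model: str,
) -> KineticFit:
    rss = float(res.chisqr)
    tss = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    p = res.params
    se = {
        "k_half_uM": (p["k_half"].stderr / NM_PER_UM) if p["k_half"].stderr else None,
        "kcat_per_min": (p["vmax"].stderr / enzyme_nM) if p["vmax"].stderr else None,
        "h": p["h"].stderr if (model == "Hill" and p["h"].stderr) else None,
    }
    return KineticFit(
        model=model,
        k_half_uM=float(p["k_half"].value) / NM_PER_UM,
        kcat_per_min=float(p["vmax"].value) / enzyme_nM,
        hill=float(p["h"].value),
        stderr=se,
        r_squared=r2,
        rss=rss,
        dof=int(res.nfree),
    )


def fit_kinetics(
    ds: KineticDataset,
    alpha: float = 0.05,
    force: bool = False,
    seed: int = 0,
) -> Tuple[KineticFit, KineticFit, ModelComparison]:
    """Fit both models and compare them by the extra-sum-of-squares F-test.

    Returns (MM fit, Hill fit, comparison).  When the dataset carries
    background replicates the n.d. screen runs first (unless ``force``) and
    an n.d. dataset is returned with flagged fits instead of parameters.
    """
    S, v = ds.substrate_nM, ds.rate
    _check_design(S)
    if not force and ds.background is not None:
        nd, reason = nd_screen(ds)
        if nd:
            empty = dict.fromkeys(("k_half_uM", "kcat_per_min", "h"))
            mk = lambda m: KineticFit(m, math.nan, math.nan, math.nan, dict(empty),
                                      math.nan, math.nan, 0, nd=True, nd_reason=reason)
            cmp_ = ModelComparison(math.nan, 1, 0, math.nan, "n.d.")
            return mk("MM"), mk("Hill"), cmp_

    res_mm = _fit_one(S, v, fix_h=True, seed=seed)
    # start the Hill fit from the MM optimum (guarantees SS_Hill <= SS_MM)
    # and from the default guesses; keep the better
    start = {name: res_mm.params[name].value for name in ("vmax", "k_half")}
    start["h"] = 1.0
    res_hill = _fit_one(S, v, fix_h=False, start=start, seed=seed)
    res_hill_alt = None
    try:
        res_hill_alt = _fit_one(S, v, fix_h=False, seed=seed + 1)
    except FitFailureError:
        pass
    if res_hill_alt is not None and res_hill_alt.chisqr < res_hill.chisqr:
        res_hill = res_hill_alt

    fit_mm = _summarize(res_mm, v, ds.enzyme_nM, "MM")
    fit_hill = _summarize(res_hill, v, ds.enzyme_nM, "Hill")
    comparison = ess_f_test(
        fit_mm.rss, fit_mm.dof, fit_hill.rss, fit_hill.dof,
        tss=float(np.sum((v - v.mean()) ** 2)), alpha=alpha,
    )
    return fit_mm, fit_hill, comparison


def ess_f_test(
    rss_restricted: float,
    dof_restricted: int,
    rss_full: float,
    dof_full: int,
    tss: float = 1.0,
    alpha: float = 0.05,
) -> ModelComparison:
    """Extra-sum-of-squares F-test for nested least-squares models.

    When both models fit to machine precision (both RSS below 1e-12 of the
    total sum of squares) the comparison is degenerate and reported as
    F = 0, p = 1 -- a ratio of two rounding errors carries no evidence.
    """
    df_num = dof_restricted - dof_full
    if df_num <= 0 or dof_full <= 0:
        raise KineticsError("full model must have fewer residual df than restricted")
    rss_full = min(rss_full, rss_restricted)  # nesting: full can't fit worse
    tiny = 1e-12 * max(tss, 1e-300)
    if rss_restricted <= tiny:
        f_stat, p = 0.0, 1.0
    elif rss_full <= tiny:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = ((rss_restricted - rss_full) / df_num) / (rss_full / dof_full)
        p = float(stats.f.sf(f_stat, df_num, dof_full))
    preferred = "Hill" if p < alpha else "MM"
    return ModelComparison(f_stat, df_num, dof_full, p, preferred)


def nd_screen(ds: KineticDataset, alpha: float = 0.05) -> Tuple[bool, str]:
    """Decide whether kinetic parameters are determinable at all.

    n.d. (not determined) when the one-sided t-test of the top-concentration
    signals against background is non-significant, or when the fitted Vmax
    confidence interval includes zero.
    """
    if ds.background is None:
        nd_ci, reason = _vmax_ci_screen(ds, alpha)
        if reason == "":
            raise KineticsError(
                "n.d. screen needs background replicates or a computable Vmax CI"
            )
        return nd_ci, reason
    bg = np.asarray(ds.background, dtype=float)
    top_S = ds.substrate_nM.max()
    top_v = ds.rate[ds.substrate_nM == top_S]
    if len(top_v) >= 2 and len(bg) >= 2:
        res = stats.ttest_ind(top_v, bg, alternative="greater")
        if res.pvalue >= alpha:
            return True, (
                f"top-concentration signal indistinguishable from background "
                f"(one-sided t, p={res.pvalue:.3g})"
            )
    nd_ci, reason = _vmax_ci_screen(ds, alpha)
    if nd_ci:
        return True, reason
    return False, "signal above background"


def _vmax_ci_screen(ds: KineticDataset, alpha: float) -> Tuple[bool, str]:
    """Vmax confidence interval from an unbounded refit.

    The production fit constrains Vmax >= 0, which pins pure-noise data to
    the bound and leaves no covariance estimate; the screen therefore refits
    with Vmax free so the interval can legitimately straddle zero.
    """
    S, v = ds.substrate_nM, ds.rate
    try:
        _check_design(S)
    except KineticsError:
        return False, ""
    vmax0, k0 = _initial_guesses(S, v)
    params = lmfit.Parameters()
    params.add("vmax", value=vmax0 if vmax0 != 0 else 1e-6)
    params.add("k_half", value=k0, min=1e-9)
    params.add("h", value=1.0, min=1e-3, max=20.0)

    def resid(p):
        return hill_velocity(S, p["k_half"].value, 1.0, p["h"].value, 1.0) * p[
            "vmax"
        ].value - v

    try:
        res = lmfit.minimize(resid, params, method="leastsq")
    except Exception:
        return False, ""
    vmax = res.params["vmax"].value
    se = res.params["vmax"].stderr
    if se is None or not np.isfinite(se):
        return False, ""
    tcrit = stats.t.ppf(1 - alpha / 2, max(res.nfree, 1))
    if vmax - tcrit * se <= 0:
        return True, f"Vmax CI includes 0 ({vmax:.3g} +/- {tcrit * se:.3g})"
    return False, "Vmax CI excludes 0"


def endpoint_compare(
    groups: Dict[str, Sequence[float]],
    pairs: Optional[Iterable[Tuple[str, str]]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise two-tailed t-tests between endpoint-assay groups."""
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        t, df, p = ttest_two_sample(groups[a], groups[b], welch=welch)
        rows.append({"group_a": a, "group_b": b, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1))


def make_titration(top: float, fold: float, n_points: int) -> List[float]:
    """Serial-dilution series: [top, top/fold, ...] to 3 sig figs, 0 appended."""
    if top <= 0:
        raise KineticsError("top concentration must be > 0")
    if fold <= 1:
        raise KineticsError("dilution fold must be > 1")
    if n_points < 2:
        raise KineticsError("need at least 2 points")
    series = [_round_sig(top / fold**i) for i in range(n_points)]
    series.append(0.0)
    return series


def read_kinetics_csv(
    path, enzyme_nM: float, specific_activity: float = 1.0, time_min: float = 1.0
) -> KineticDataset:
    """Load (substrate_nM, signal, replicate[, background]) CSV.

    Rows flagged background (boolean column) become blank replicates; the
    signal column is converted to a rate via counts x factor / time when a
    conversion is supplied, otherwise taken as a rate directly.
    """
    df = pd.read_csv(path)
    required = {"substrate_nM", "signal"}
    if not required <= set(df.columns):
        raise KineticsError(f"CSV needs columns {sorted(required)}")
    is_bg = df["background"].astype(bool) if "background" in df.columns else (
        pd.Series(False, index=df.index)
    )
    fg = df[~is_bg]
    rate = fg["signal"].to_numpy(dtype=float) * specific_activity / time_min
    bg = df.loc[is_bg, "signal"].to_numpy(dtype=float) * specific_activity / time_min
    return KineticDataset(
        substrate_nM=fg["substrate_nM"].to_numpy(dtype=float),
        rate=rate,
        enzyme_nM=enzyme_nM,
        replicate=fg["replicate"].to_numpy() if "replicate" in fg.columns else None,
        background=bg if len(bg) else None,
    )
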