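"""Binding-curve analysis: 4PL fits, relative EC50, EC_F^rel, hook exclusion.

Alpha-bead binding series (counts vs query concentration) are fitted with
the four-parameter logistic

    y(Q) = bottom + (top - bottom) / (1 + (EC50 / Q)^H)

after excluding points beyond the hook point -- the concentration past which
signal drops because query exceeds bead saturation.  EC50rel is the fitted
inflection concentration between the (unconstrained) plateaus; the
generalized response concentration is

    EC_F^rel = (F / (100 - F))^(1/H) x EC50rel,   0 < F < 100,

so EC80rel (F = 80) is the standard probing concentration.  Fold differences
in EC50rel between targets carry first-order propagated uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd

from .simulate import four_pl


class DoseResponseError(ValueError):
    pass


class NoBindingError(DoseResponseError):
    """Flat series: minimal interaction, fit refused."""


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50_rel: float
    hillslope: float
    r_squared: float
    stderr: Dict[str, Optional[float]]
    excluded: Tuple[int, ...] = ()
    no_binding: bool = False
    target: str = ""

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "no_binding": self.no_binding,
            "bottom": self.bottom,
            "top": self.top,
            "EC50_rel_nM": self.ec50_rel,
            "hillslope": self.hillslope,
            "R2": self.r_squared,
            "stderr": self.stderr,
            "excluded_indices": list(self.excluded),
        }


def exclude_hook(
    query_nM: Sequence[float],
    counts: Sequence[float],
    hook_frac: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray, Tuple[int, ...]]:
    """Drop points beyond the hook point.

    Let q* be the concentration of maximal mean signal.  Points with Q > q*
    are excluded iff their mean signal falls below (1 - hook_frac) x the
    maximal mean signal.  Returns (kept Q, kept counts, excluded indices into
    the input arrays).
    """
    Q = np.asarray(query_nM, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(Q) < 3:
        raise DoseResponseError("need at least 3 points")
    levels = np.unique(Q)
    means = np.array([y[Q == q].mean() for q in levels])
    q_star = levels[int(np.argmax(means))]
    y_max = means.max()
    bad_levels = {
        q
        for q, m in zip(levels, means)
        if q > q_star and m < (1.0 - hook_frac) * y_max
    }
    excluded = tuple(i for i, q in enumerate(Q) if q in bad_levels)
    keep = np.array([i not in excluded for i in range(len(Q))])
    if not keep.any():
        raise DoseResponseError("hook exclusion removed every point")
    return Q[keep], y[keep], excluded


def fit_4pl(
    query_nM: Sequence[float],
    counts: Sequence[float],
    hook_frac: Optional[float] = 0.1,
    fix_bottom: Optional[float] = None,
    noise_floor: float = 0.0,
    target: str = "",
    seed: int = 0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of a (hook-excluded) binding series.

    Duplicate readings at the same concentration are all retained in the
    residuals.  Flat series (max - min <= noise floor) are refused and
    flagged ``no_binding`` via :class:`NoBindingError`; the default noise
    floor of 0 refuses only exactly constant data.
    """
    if hook_frac is not None:
        Q, y, excluded = exclude_hook(query_nM, counts, hook_frac)
    else:
        Q = np.asarray(query_nM, dtype=float)
        y = np.asarray(counts, dtype=float)
        excluded = ()
    if len(np.unique(Q[Q > 0])) < 5:
        raise DoseResponseError("need >= 5 distinct non-zero concentrations")
    spread = float(y.max() - y.min())
    if spread <= noise_floor:
        raise NoBindingError(
            f"signal spread {spread:.3g} within noise floor {noise_floor:.3g}"
        )

    pos = Q > 0
    ec50_0 = float(np.median(Q[pos]))
    params = lmfit.Parameters()
    params.add("bottom", value=float(y.min()), vary=fix_bottom is None)
    if fix_bottom is not None:
        params["bottom"].value = fix_bottom
    params.add("top", value=float(y.max()))
    params.add("log_ec50", value=math.log(ec50_0))
    params.add("hillslope", value=1.0, min=1e-3, max=20.0)

    def resid(p):
        return (
            four_pl(Q, p["bottom"].value, p["top"].value,
                    math.exp(p["log_ec50"].value), p["hillslope"].value)
            - y
        )

    rng = np.random.default_rng(seed)
    res = None
    for attempt in range(6):
        try:
            cand = lmfit.minimize(resid, params, method="leastsq")
            if cand.success and (res is None or cand.chisqr < res.chisqr):
                res = cand
                break
        except Exception:
            pass
        params["log_ec50"].value = math.log(ec50_0) + rng.normal(0, 1.5)
        params["hillslope"].value = rng.uniform(0.3, 3.0)
    if res is None:
        raise DoseResponseError("4PL fit did not converge")

    p = res.params
    ec50 = math.exp(p["log_ec50"].value)
    # delta-method SE for EC50 from the log-parameterized fit
    se_ec50 = ec50 * p["log_ec50"].stderr if p["log_ec50"].stderr else None
    rss = float(res.chisqr)
    tss = float(np.sum((y - y.mean()) ** 2))
    fit = DoseResponseFit(
        bottom=float(p["bottom"].value),
        top=float(p["top"].value),
        ec50_rel=ec50,
        hillslope=float(p["hillslope"].value),
        r_squared=1.0 - rss / tss if tss > 0 else 1.0,
        stderr={
            "bottom": p["bottom"].stderr,
            "top": p["top"].stderr,
            "ec50_rel": se_ec50,
            "hillslope": p["hillslope"].stderr,
        },
        excluded=excluded,
        target=target,
    )
    if fit.top <= fit.bottom:
        raise NoBindingError("fitted top <= bottom: no concentration-dependent signal")
    return fit


def ec_f_rel(fit: DoseResponseFit, f_percent: float) -> float:
    """EC_F^rel = (F/(100-F))^(1/H) x EC50rel; F = 50 returns EC50rel itself."""
    if not 0 < f_percent < 100:
        raise DoseResponseError("F must be strictly between 0 and 100")
    if fit.no_binding:
        raise NoBindingError("no-binding fit has no EC_F")
    return (f_percent / (100.0 - f_percent)) ** (1.0 / fit.hillslope) * fit.ec50_rel


def compare_targets(
    fit_a: DoseResponseFit, fit_b: DoseResponseFit
) -> Tuple[float, Optional[float]]:
    """Fold difference EC50rel(A)/EC50rel(B) with first-order propagated SE."""
    if fit_a.no_binding or fit_b.no_binding:
        raise NoBindingError("cannot compare: a fit is flagged no-binding")
    fold = fit_a.ec50_rel / fit_b.ec50_rel
    se_a = fit_a.stderr.get("ec50_rel")
    se_b = fit_b.stderr.get("ec50_rel")
    if se_a is None or se_b is None:
        return fold, None
    se = fold * math.sqrt(
        (se_a / fit_a.ec50_rel) ** 2 + (se_b / fit_b.ec50_rel) ** 2
    )
    return fold, se


def fit_binding_table(
    df: pd.DataFrame,
    hook_frac: float = 0.1,
    f_list: Sequence[float] = (80.0,),
    noise_floor: float = 0.0,
) -> List[dict]:
    """Fit every target in a (query_nM, counts, target, replicate) table.

    Returns one JSON-ready record per target with the 4PL parameters,
    EC_F^rel values and hook exclusions; no-binding targets are flagged
    instead of fitted.
    """
    out = []
    for target, g in df.groupby("target"):
        try:
            fit = fit_4pl(
                g["query_nM"].to_numpy(),
                g["counts"].to_numpy(),
                hook_frac=hook_frac,
                noise_floor=noise_floor,
                target=str(target),
            )
            rec = fit.to_dict()
            for f in f_list:
                rec[f"EC{f:g}_rel_nM"] = ec_f_rel(fit, f)
        except NoBindingError as exc:
            rec = {"target": str(target), "no_binding": True, "reason": str(exc)}
        out.append(rec)
    return out
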