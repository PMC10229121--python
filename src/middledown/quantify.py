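"""Targeted C4+1 quantification: scan selection, averaging, stoichiometry.

The pipeline mirrors a targeted ion-trap acquisition analysis: MS2 scans are
assigned to an H3 acetyl degree by retention-time window (the primary
classifier) with the precursor m/z as a coarse confirmation, averaged on a
fixed m/z bin grid, and the K4 methyl stoichiometry read out as the relative
intensity of the four C4+1 targets (nominal 474/488/502/516 Th), normalized
to 100 %.  Technical replicates are averaged within each biological
replicate before the across-biological mean and SEM are formed, and
conditions are compared per cell with a two-tailed two-sample t-test.

Note on the near-isobaric me3/ac pair: trimethyl and acetyl differ by only
0.036385 Da (0.0040 Th at 9+), so precursor filtering alone cannot separate
e.g. 3ac+K4me3 from 4ac+K4me0 -- exactly why RT windows lead and the
precursor match is a confirmation, not a classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .proteoforms import c4_targets
from .simulate import DEFAULT_RT_WINDOWS, Run, degree_precursors

ME_STATES = ("me0", "me1", "me2", "me3")


class EmptyWindowError(RuntimeError):
    """No MS2 scan survived selection for this acetyl-degree window."""

    def __init__(self, degree: int, n_in_rt: int, n_precursor: int, n_snr: int):
        self.degree = degree
        self.n_in_rt = n_in_rt
        self.n_precursor = n_precursor
        self.n_snr = n_snr
        super().__init__(
            f"degree {degree}: {n_in_rt} scans in RT window, "
            f"{n_precursor} after precursor filter, {n_snr} after SNR filter"
        )


class UndefinedStoichiometryError(RuntimeError):
    """All four C4+1 target intensities are zero."""


@dataclass(frozen=True)
class AcetylStateWindow:
    """Selection rule for one acetyl degree."""

    degree: int
    rt_interval: Tuple[float, float]  # half-open [start, end), minutes
    precursor_targets: Tuple[float, ...]  # [M+9H]9+ across K4 me0..me3
    precursor_tol: float = 0.05  # Th
    fragment_tol: float = 0.3  # Th

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if len(self.precursor_targets) != 4:
            raise ValueError("expected 4 precursor targets (K4 me0..me3)")


def default_windows(
    rt_windows: Dict[int, Tuple[float, float]] = DEFAULT_RT_WINDOWS,
    precursor_tol: float = 0.05,
    fragment_tol: float = 0.3,
    charge: int = 9,
) -> Dict[int, AcetylStateWindow]:
    """One :class:`AcetylStateWindow` per acetyl degree, from the RT map."""
    return {
        a: AcetylStateWindow(
            degree=a,
            rt_interval=iv,
            precursor_targets=degree_precursors(a, charge=charge),
            precursor_tol=precursor_tol,
            fragment_tol=fragment_tol,
        )
        for a, iv in sorted(rt_windows.items())
    }


@dataclass
class AveragedSpectrum:
    """Mean binned MS2 spectrum for one acetyl degree."""

    degree: int
    grid_mz: np.ndarray
    mean_intensity: np.ndarray
    n_scans: int


def select_and_average(
    run: Run,
    window: AcetylStateWindow,
    snr_min: float = 3.0,
    bin_width: float = 0.1,
    grid_range: Tuple[float, float] = (470.0, 530.0),
) -> AveragedSpectrum:
    """Select MS2 scans for one acetyl degree and average them on a bin grid.

    A scan is kept when (i) its retention time falls in the half-open RT
    window, (ii) its precursor target is within tolerance of one of the
    degree's four theoretical [M+9H]9+ values, and (iii) its summed intensity
    at the four C4+1 targets is at least ``snr_min`` times the median
    off-target intensity (the deterministic stand-in for manual curation of
    low-signal scans).  Surviving scans are averaged bin-wise.
    """
    ms2 = run.ms2_scans()
    if not ms2:
        raise EmptyWindowError(window.degree, 0, 0, 0)
    lo, hi = window.rt_interval
    in_rt = [s for s in ms2 if lo <= s.rt_min < hi]
    targets = np.asarray(window.precursor_targets)
    in_prec = [
        s
        for s in in_rt
        if s.precursor_mz is not None
        and np.min(np.abs(targets - s.precursor_mz)) <= window.precursor_tol
    ]
    frag = np.asarray(c4_targets())
    kept = []
    for s in in_prec:
        on = np.zeros(4)
        off_mask = np.ones(len(s.mz), dtype=bool)
        for i, t in enumerate(frag):
            m = np.abs(s.mz - t) <= window.fragment_tol
            if m.any():
                on[i] = s.intensity[m].max()
            off_mask &= ~m
        off = s.intensity[off_mask]
        noise = float(np.median(off)) if off.size else 0.0
        if on.sum() >= snr_min * noise and on.sum() > 0:
            kept.append(s)
    if not kept:
        raise EmptyWindowError(window.degree, len(in_rt), len(in_prec), 0)

    edges = np.arange(grid_range[0], grid_range[1] + bin_width, bin_width)
    centres = (edges[:-1] + edges[1:]) / 2.0
    acc = np.zeros(len(centres))
    for s in kept:
        binned = np.zeros(len(centres))
        idx = np.clip(np.searchsorted(edges, s.mz, side="right") - 1, 0, len(centres) - 1)
        inside = (s.mz >= edges[0]) & (s.mz < edges[-1])
        np.add.at(binned, idx[inside], s.intensity[inside])
        acc += binned
    return AveragedSpectrum(
        degree=window.degree,
        grid_mz=centres,
        mean_intensity=acc / len(kept),
        n_scans=len(kept),
    )


def extract_stoichiometry(
    spec: AveragedSpectrum,
    targets: Sequence[float] = None,
    fragment_tol: float = 0.3,
    mode: str = "max",
) -> np.ndarray:
    """K4 me0..me3 percentages from the four C4+1 target intensities.

    The intensity per target is the maximum (default) or sum of binned
    intensity within ``fragment_tol``; percentages are 100 x intensity over
    the four-target total.
    """
    if targets is None:
        targets = c4_targets()
    targets = np.asarray(targets, dtype=float)
    if not np.all(np.diff(targets) > 0):
        raise ValueError("targets must be strictly increasing")
    if fragment_tol >= np.min(np.diff(targets)) / 2.0:
        raise ValueError("fragment tolerance must be < half the target spacing")
    intensities = np.zeros(4)
    for i, t in enumerate(targets):
        m = np.abs(spec.grid_mz - t) <= fragment_tol
        if m.any():
            vals = spec.mean_intensity[m]
            intensities[i] = vals.max() if mode == "max" else vals.sum()
    total = intensities.sum()
    if total <= 0:
        raise UndefinedStoichiometryError(
            f"no C4+1 signal for degree {spec.degree}"
        )
    return 100.0 * intensities / total


def quantify_run(
    run: Run,
    windows: Optional[Dict[int, AcetylStateWindow]] = None,
    snr_min: float = 3.0,
    bin_width: float = 0.1,
    mode: str = "max",
) -> pd.DataFrame:
    """Per-acetyl-degree K4 stoichiometry for one run (tidy long format).

    Degrees whose window selects no scans are reported as missing rows
    (NaN percentages), never as zeros.
    """
    windows = windows if windows is not None else default_windows()
    rows = []
    meta = run.metadata
    for degree, window in sorted(windows.items()):
        try:
            spec = select_and_average(run, window, snr_min=snr_min, bin_width=bin_width)
            pct = extract_stoichiometry(spec, fragment_tol=window.fragment_tol, mode=mode)
            n_scans = spec.n_scans
        except (EmptyWindowError, UndefinedStoichiometryError):
            pct = np.full(4, np.nan)
            n_scans = 0
        for state, p in zip(ME_STATES, pct):
            rows.append(
                {
                    "condition": meta.get("condition", ""),
                    "time_min": meta.get("time_min", np.nan),
                    "bio_rep": meta.get("bio_rep", 1),
                    "tech_rep": meta.get("tech_rep", 1),
                    "acetyl_degree": degree,
                    "me_state": state,
                    "pct": p,
                    "n_scans": n_scans,
                }
            )
    return pd.DataFrame(rows)


def aggregate_replicates(per_run: pd.DataFrame) -> pd.DataFrame:
    """Technical-within-biological aggregation into a stoichiometry table.

    Technical replicates are averaged within each biological replicate
    first; the mean and SEM (sample SD / sqrt(n)) are then computed across
    biological replicates, with n = number of biological replicates carrying
    data for the cell.  A single biological replicate yields SEM = NaN (the
    not-available marker).  Each (condition, time, degree) row re-normalizes
    to exactly 100 % across me0..me3.
    """
    required = {"condition", "time_min", "bio_rep", "acetyl_degree", "me_state", "pct"}
    missing = required - set(per_run.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bio = (
        per_run.groupby(
            ["condition", "time_min", "bio_rep", "acetyl_degree", "me_state"],
            dropna=False,
        )["pct"]
        .mean()
        .reset_index()
    )
    def _cell(g: pd.DataFrame) -> pd.Series:
        vals = g["pct"].dropna().to_numpy()
        n = len(vals)
        if n == 0:
            return pd.Series({"mean_pct": np.nan, "sem": np.nan, "n": 0})
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"mean_pct": mean, "sem": sem, "n": n})

    table = (
        bio.groupby(
            ["condition", "time_min", "acetyl_degree", "me_state"], dropna=False
        )
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    # renormalize each degree row to 100 % (means of ratios need not sum exactly)
    def _norm(g: pd.DataFrame) -> pd.DataFrame:
        tot = g["mean_pct"].sum()
        if np.isfinite(tot) and tot > 0:
            scale = 100.0 / tot
            g = g.assign(mean_pct=g["mean_pct"] * scale, sem=g["sem"] * scale)
        return g

    table = (
        table.groupby(["condition", "time_min", "acetyl_degree"], dropna=False)
        .apply(_norm, include_groups=False)
        .reset_index()
        .drop(columns=["level_3"], errors="ignore")
    )
    table["n"] = table["n"].astype(int)
    return table


def bio_replicate_values(per_run: pd.DataFrame) -> pd.DataFrame:
    """Biological-replicate-level percentages (tech reps averaged), tidy."""
    return (
        per_run.groupby(
            ["condition", "time_min", "bio_rep", "acetyl_degree", "me_state"],
            dropna=False,
        )["pct"]
        .mean()
        .reset_index()
    )


def ttest_two_sample(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> Tuple[float, float, float]:
    """Two-tailed two-sample t-test; returns (t, df, p).

    Default is the Student pooled-variance variant; ``welch=True`` uses the
    unequal-variance form.  Zero variance in both groups with equal means is
    p = 1 by convention; zero variance with unequal means is degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return float(res.statistic), df, float(res.pvalue)


def compare_conditions(
    bio_a: pd.DataFrame,
    bio_b: pd.DataFrame,
    cells: Optional[Iterable[Tuple[float, int, str]]] = None,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-cell two-tailed t-tests between two conditions.

    Inputs are biological-replicate-level tables (see
    :func:`bio_replicate_values`).  ``cells`` selects (time_min,
    acetyl_degree, me_state) triples; by default every cell present in both
    tables is tested.  Returns a tidy table of (t, df, p); optional
    Benjamini-Hochberg adjusted q-values with ``fdr=True``.
    """
    keys = ["time_min", "acetyl_degree", "me_state"]
    if cells is None:
        # auto-discovery tests every cell with >= 2 measured bio reps on
        # both sides; missing-data cells (NaN percentages) are skipped
        def _testable(df):
            counts = df.dropna(subset=["pct"]).groupby(keys).size()
            return set(counts[counts >= 2].index)

        cells = sorted(_testable(bio_a) & _testable(bio_b))
    rows = []
    for time_min, degree, state in cells:
        va = bio_a.query(
            "time_min == @time_min and acetyl_degree == @degree and me_state == @state"
        )["pct"].dropna()
        vb = bio_b.query(
            "time_min == @time_min and acetyl_degree == @degree and me_state == @state"
        )["pct"].dropna()
        t, df, p = ttest_two_sample(va, vb, welch=welch)
        rows.append(
            {
                "time_min": time_min,
                "acetyl_degree": degree,
                "me_state": state,
                "t": t,
                "df": df,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["q"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q
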