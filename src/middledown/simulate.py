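"""Ground-truth-labelled synthetic data for every pipeline stage.

Three generators live here:

* :func:`simulate_run` / :func:`simulate_timecourse` emit targeted
  middle-down acquisitions: H3 acetyl states (0ac-5ac) elute as
  chromatographically separated bell-shaped peaks inside their retention-time
  windows; each ion-trap MS2 scan carries the four C4+1 K4-readout peaks with
  intensities proportional to abundance x K4 stoichiometry, under a
  multiplicative lognormal noise model plus an additive baseline.
* :func:`simulate_kinetics` draws steady-state velocity titrations from the
  Hill equation v = kcat*E*S^h / (K05^h + S^h) with Gaussian noise.
* :func:`simulate_binding` draws AlphaScreen-style binding series from a 4PL
  curve, optionally with post-peak hook suppression (signal inhibition once
  the query exceeds bead saturation).

Every generator takes an explicit seed and is bit-deterministic under it.
Runs serialize to an exact internal JSON format (the primary fixture format)
and to centroided mzML.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .proteoforms import (
    H3_1_50,
    K4_ACETYL_SITES,
    Proteoform,
    c4_targets,
    ion_mz,
)

K4_STATES = ("me0", "me1", "me2", "me3")

#: Retention-time windows (min) per acetyl degree.  1ac/2ac share the 55 min
#: boundary; windows are half-open [start, end) so a scan at exactly 55.0
#: belongs to 2ac.
DEFAULT_RT_WINDOWS: Dict[int, Tuple[float, float]] = {
    0: (35.0, 40.0),
    1: (45.0, 55.0),
    2: (55.0, 60.0),
    3: (62.0, 68.0),
    4: (69.0, 73.0),
    5: (74.0, 78.0),
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class MixtureSpec:
    """Per acetyl degree: abundance and K4 methyl stoichiometry.

    ``abundances[a]`` is an arbitrary intensity scale (>= 0) for acetyl
    degree ``a``; ``k4[a]`` is the (me0, me1, me2, me3) fractional occupancy,
    summing to 1.
    """

    abundances: Dict[int, float]
    k4: Dict[int, Tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.abundances.values()):
            raise SimulationError("at least one acetyl degree needs abundance > 0")
        for a, ab in self.abundances.items():
            if ab < 0:
                raise SimulationError(f"negative abundance for degree {a}")
            if a not in self.k4:
                raise SimulationError(f"no K4 stoichiometry for degree {a}")
            pi = self.k4[a]
            if len(pi) != 4 or any(p < 0 for p in pi):
                raise SimulationError(f"K4 stoichiometry for degree {a} invalid")
            if abs(sum(pi) - 1.0) > 1e-12:
                raise SimulationError(
                    f"K4 stoichiometry for degree {a} sums to {sum(pi)}, not 1"
                )

    def to_dict(self) -> dict:
        return {
            "abundances": {str(a): float(v) for a, v in self.abundances.items()},
            "k4": {str(a): [float(p) for p in pi] for a, pi in self.k4.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            abundances={int(a): float(v) for a, v in d["abundances"].items()},
            k4={int(a): tuple(map(float, pi)) for a, pi in d["k4"].items()},
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument-side parameters of the simulated targeted acquisition."""

    rt_windows: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RT_WINDOWS)
    )
    ms1_range: Tuple[float, float] = (585.0, 640.0)
    ms2_range: Tuple[float, float] = (470.0, 530.0)
    scan_interval_s: float = 2.0
    peak_width_min: float = 1.0  # SD of the chromatographic bell
    noise_cv: float = 0.0  # multiplicative lognormal CV on peak intensities
    baseline: float = 0.0  # additive baseline peak intensity scale
    n_baseline_peaks: int = 12
    isotope_envelope: bool = False  # binomial 13C envelope instead of sticks
    charge: int = 9

    def __post_init__(self) -> None:
        for a, (lo, hi) in self.rt_windows.items():
            if not (0 <= a <= 5) or lo >= hi:
                raise SimulationError(f"malformed RT window {a}: ({lo}, {hi})")
        for rng_ in (self.ms1_range, self.ms2_range):
            if rng_[0] <= 0 or rng_[0] >= rng_[1]:
                raise SimulationError(f"malformed scan range {rng_}")
        if self.scan_interval_s <= 0 or self.peak_width_min <= 0:
            raise SimulationError("scan interval and peak width must be > 0")


@dataclass
class Scan:
    level: int  # 1 or 2
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_width: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "rt_min": self.rt_min,
            "mz": [float(x) for x in self.mz],
            "intensity": [float(x) for x in self.intensity],
        }
        if self.level == 2:
            d["precursor_mz"] = self.precursor_mz
            d["isolation_width"] = self.isolation_width
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scan":
        return cls(
            level=int(d["level"]),
            rt_min=float(d["rt_min"]),
            mz=np.asarray(d["mz"], dtype=float),
            intensity=np.asarray(d["intensity"], dtype=float),
            precursor_mz=d.get("precursor_mz"),
            isolation_width=d.get("isolation_width"),
        )


@dataclass
class Run:
    """An ordered acquisition: MS1/MS2 scans plus replicate/condition labels."""

    scans: List[Scan]
    metadata: Dict[str, object] = field(default_factory=dict)

    def ms2_scans(self) -> List[Scan]:
        return [s for s in self.scans if s.level == 2]

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "scans": [s.to_dict() for s in self.scans],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Run":
        return cls(
            scans=[Scan.from_dict(s) for s in d["scans"]],
            metadata=dict(d.get("metadata", {})),
        )


# ---------------------------------------------------------------------------
# precursor targets

def degree_precursors(
    degree: int, sequence: str = H3_1_50, charge: int = 9
) -> Tuple[float, float, float, float]:
    """Theoretical [M+zH]z+ m/z for one acetyl degree across K4 me0..me3.

    All acetyl-site placements of a given degree are isobaric, so the first
    ``degree`` sites of K9/K14/K18/K23/K27 stand in for the class.
    """
    sites = K4_ACETYL_SITES[:degree]
    out = []
    for state in K4_STATES:
        ptms = {(pos, "ac") for pos in sites}
        if state != "me0":
            ptms.add((4, state))
        out.append(ion_mz(Proteoform(sequence, frozenset(ptms)), "precursor", 0, charge))
    return tuple(out)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    s2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=n))


_C13_DELTA = 1.0033548


def _isotope_peaks(mz0: float, inten: float, charge: int, n_carbon: int) -> tuple:
    """Binomial carbon-13 envelope (p = 0.0107 per carbon), first 5 isotopologues."""
    from scipy.stats import binom

    k = np.arange(5)
    w = binom.pmf(k, n_carbon, 0.0107)
    return mz0 + k * _C13_DELTA / charge, inten * w / w[0]


def simulate_run(
    mix: MixtureSpec,
    cfg: AcquisitionConfig = AcquisitionConfig(),
    seed: int = 0,
    metadata: Optional[dict] = None,
) -> Tuple[Run, MixtureSpec]:
    """Simulate one targeted acquisition; returns the run and a ground-truth copy.

    MS2 scans exist only inside the RT windows of acetyl degrees with
    abundance > 0.  Each MS2 scan carries the four C4+1 peaks with expected
    intensities abundance x pi x bell(rt), perturbed by lognormal noise; its
    precursor target is one of the degree's four theoretical [M+9H]9+ values,
    drawn with probability pi (the targeted list cycles over K4 states).
    With ``noise_cv = 0`` and ``baseline = 0`` intensities are exactly
    proportional to the ground truth.
    """
    rng = np.random.default_rng(seed)
    targets = np.asarray(c4_targets())
    scans: List[Scan] = []
    step = cfg.scan_interval_s / 60.0
    for degree in sorted(a for a, v in mix.abundances.items() if v > 0):
        lo, hi = cfg.rt_windows[degree]
        centre, sigma = (lo + hi) / 2.0, cfg.peak_width_min
        precursors = np.asarray(degree_precursors(degree, charge=cfg.charge))
        pi = np.asarray(mix.k4[degree])
        abundance = mix.abundances[degree]
        times = np.arange(lo, hi - 1e-9, step)
        for t in times:
            bell = float(np.exp(-0.5 * ((t - centre) / sigma) ** 2))
            base_int = abundance * pi * bell
            # MS1: stick per K4 state at the degree's precursor m/z
            ms1_int = base_int * _lognormal_factors(rng, cfg.noise_cv, 4)
            order = np.argsort(precursors)
            scans.append(
                Scan(1, float(t), precursors[order], ms1_int[order])
            )
            # MS2: all four C4 targets in one spectrum
            frag_int = base_int * _lognormal_factors(rng, cfg.noise_cv, 4)
            mzs, ints = list(targets), list(frag_int)
            if cfg.isotope_envelope:
                mzs2, ints2 = [], []
                for m0, i0 in zip(mzs, ints):
                    em, ei = _isotope_peaks(m0, i0, 1, 21)
                    mzs2.extend(em)
                    ints2.extend(ei)
                mzs, ints = mzs2, ints2
            if cfg.baseline > 0:
                bl_mz = rng.uniform(*cfg.ms2_range, size=cfg.n_baseline_peaks)
                bl_int = rng.uniform(0, cfg.baseline, size=cfg.n_baseline_peaks)
                mzs = list(mzs) + list(bl_mz)
                ints = list(ints) + list(bl_int)
            mz_arr = np.asarray(mzs, dtype=float)
            in_arr = np.asarray(ints, dtype=float)
            order = np.argsort(mz_arr)
            pick = int(rng.choice(4, p=pi / pi.sum()))
            scans.append(
                Scan(
                    2,
                    float(t),
                    mz_arr[order],
                    in_arr[order],
                    precursor_mz=float(precursors[pick]),
                    isolation_width=1.0,
                )
            )
    scans.sort(key=lambda s: (s.rt_min, s.level))
    run = Run(scans=scans, metadata=dict(metadata or {}))
    truth = replace(mix)
    return run, truth


def _perturb_mixture(
    mix: MixtureSpec, bio_cv: float, rng: np.random.Generator
) -> MixtureSpec:
    """Biological-replicate perturbation: lognormal jitter, stoichiometry renormalized."""
    if bio_cv <= 0:
        return mix
    ab = {}
    k4 = {}
    for a, v in mix.abundances.items():
        ab[a] = float(v * _lognormal_factors(rng, bio_cv, 1)[0])
        pi = np.asarray(mix.k4[a]) * _lognormal_factors(rng, bio_cv, 4)
        pi = pi / pi.sum()
        k4[a] = tuple(float(x) for x in pi)
    return MixtureSpec(ab, k4)


def simulate_timecourse(
    trajectory: Sequence[Tuple[float, MixtureSpec]],
    cfg: AcquisitionConfig = AcquisitionConfig(),
    n_bio: int = 3,
    n_tech: int = 2,
    seed: int = 0,
    bio_cv: float = 0.0,
    condition: str = "treated",
) -> List[Tuple[Run, MixtureSpec]]:
    """Labelled replicate runs along a treatment time course.

    Biological replicates redraw the mixture (lognormal ``bio_cv``);
    technical replicates redraw only acquisition noise.  Returns
    ``len(trajectory) * n_bio * n_tech`` (run, truth) pairs, each run labelled
    with condition, time point and replicate ids.
    """
    if not trajectory:
        raise SimulationError("empty trajectory")
    if n_bio < 1 or n_tech < 1:
        raise SimulationError("need n_bio >= 1 and n_tech >= 1")
    ss = np.random.SeedSequence(seed)
    out: List[Tuple[Run, MixtureSpec]] = []
    for (time_min, mix), ss_time in zip(trajectory, ss.spawn(len(trajectory))):
        for bio, ss_bio in enumerate(ss_time.spawn(n_bio), start=1):
            children = ss_bio.spawn(n_tech + 1)
            bio_mix = _perturb_mixture(
                mix, bio_cv, np.random.default_rng(children[0])
            )
            for tech in range(1, n_tech + 1):
                child_seed = int(children[tech].generate_state(1)[0] % (2**31))
                run, truth = simulate_run(
                    bio_mix,
                    cfg,
                    seed=child_seed,
                    metadata={
                        "condition": condition,
                        "time_min": float(time_min),
                        "bio_rep": bio,
                        "tech_rep": tech,
                    },
                )
                out.append((run, truth))
    return out


# ---------------------------------------------------------------------------
# kinetics / binding generators

def hill_velocity(S, k_half: float, kcat: float, h: float, enzyme: float):
    """v(S) = kcat*E*S^h / (K05^h + S^h); Michaelis-Menten is h = 1."""
    if k_half <= 0 or h <= 0:
        raise SimulationError("K05 and h must be > 0")
    S = np.asarray(S, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = kcat * enzyme * S**h / (k_half**h + S**h)
    return np.where(S > 0, v, 0.0)


def simulate_kinetics(
    k_half: float,
    kcat: float,
    h: float,
    enzyme: float,
    substrate: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_rep: int = 1,
) -> pd.DataFrame:
    """Velocity titration table (substrate_nM, rate, replicate) from the Hill model.

    Units follow the assay convention: substrate and K05 in nM, rate in
    signal min^-1 (kcat in min^-1 times enzyme concentration).  Gaussian
    noise with absolute SD ``noise_sd`` is added per observation.
    """
    if enzyme <= 0:
        raise SimulationError("enzyme concentration must be > 0")
    S = np.asarray(substrate, dtype=float)
    if (S < 0).any():
        raise SimulationError("substrate concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        v = hill_velocity(S, k_half, kcat, h, enzyme)
        if noise_sd > 0:
            v = v + rng.normal(0, noise_sd, size=v.shape)
        rows.append(
            pd.DataFrame(
                {"substrate_nM": S, "rate": v, "replicate": rep}
            )
        )
    return pd.concat(rows, ignore_index=True)


def four_pl(Q, bottom: float, top: float, ec50: float, hillslope: float):
    """y(Q) = bottom + (top - bottom) / (1 + (EC50/Q)^H); y(0) = bottom."""
    Q = np.asarray(Q, dtype=float)
    with np.errstate(divide="ignore"):
        y = bottom + (top - bottom) / (1.0 + (ec50 / Q) ** hillslope)
    return np.where(Q > 0, y, bottom)


def simulate_binding(
    bottom: float,
    top: float,
    ec50: float,
    hillslope: float,
    query: Sequence[float],
    noise_cv: float = 0.0,
    hook: Optional[Tuple[float, float]] = None,
    seed: int = 0,
    n_rep: int = 2,
    target: str = "target",
) -> pd.DataFrame:
    """Alpha-count binding series (query_nM, counts, target, replicate) from a 4PL.

    ``hook=(onset_nM, power)`` enables post-peak suppression: counts are
    multiplied by 1 / (1 + (Q/onset)^power), emulating bead saturation at
    high query concentration.
    """
    if ec50 <= 0 or hillslope <= 0:
        raise SimulationError("EC50 and hillslope must be > 0")
    Q = np.asarray(query, dtype=float)
    if (Q < 0).any():
        raise SimulationError("query concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        y = four_pl(Q, bottom, top, ec50, hillslope)
        if hook is not None:
            onset, power = hook
            y = y / (1.0 + (Q / onset) ** power)
        y = y * _lognormal_factors(rng, noise_cv, len(Q))
        rows.append(
            pd.DataFrame(
                {"query_nM": Q, "counts": y, "target": target, "replicate": rep}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O: internal JSON (exact), mzML (centroided), ground-truth YAML sidecar

def write_run_json(run: Run, path) -> None:
    with open(path, "w") as fh:
        json.dump(run.to_dict(), fh, indent=None, separators=(",", ":"))


def read_run_json(path) -> Run:
    with open(path) as fh:
        return Run.from_dict(json.load(fh))


def write_truth_yaml(mix: MixtureSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mix.to_dict(), fh, sort_keys=True)


def read_truth_yaml(path) -> MixtureSpec:
    with open(path) as fh:
        return MixtureSpec.from_dict(yaml.safe_load(fh))


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *map(float, values))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription><fileContent>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
  </fileContent></fileDescription>
  <run id="run">
    <spectrumList count="{count}">
"""


def write_mzml(run: Run, path) -> None:
    """Write the run as centroided mzML (zlib-compressed 64-bit arrays)."""
    parts = [_MZML_HEADER.format(count=len(run.scans))]
    for i, s in enumerate(run.scans):
        mz64 = _b64_doubles(s.mz)
        in64 = _b64_doubles(s.intensity)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s.mz)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.level}"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f"        <scanList count=\"1\"><scan>\n"
            f'          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt_min!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            f"        </scan></scanList>\n"
        )
        if s.level == 2:
            parts.append(
                f"        <precursorList count=\"1\"><precursor>\n"
                f"          <isolationWindow>\n"
                f'            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{s.precursor_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f'            <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{(s.isolation_width or 1.0) / 2!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f'            <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{(s.isolation_width or 1.0) / 2!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f"          </isolationWindow>\n"
                f"          <selectedIonList count=\"1\"><selectedIon>\n"
                f'            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f"          </selectedIon></selectedIonList>\n"
                f"          <activation>\n"
                f'            <cvParam cvRef="MS" accession="MS:1000598" name="electron transfer dissociation" value=""/>\n'
                f"          </activation>\n"
                f"        </precursor></precursorList>\n"
            )
        parts.append(
            f"        <binaryDataArrayList count=\"2\">\n"
            f'          <binaryDataArray encodedLength="{len(mz64)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f"            <binary>{mz64}</binary>\n"
            f"          </binaryDataArray>\n"
            f'          <binaryDataArray encodedLength="{len(in64)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
            f"            <binary>{in64}</binary>\n"
            f"          </binaryDataArray>\n"
            f"        </binaryDataArrayList>\n"
            f"      </spectrum>\n"
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))


_NS = "{http://psi.hupo.org/ms/mzml}"

# CV accessions this reader understands (the subset the writer emits)
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_ZLIB = "MS:1000574"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"


def _decode_binary(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    node = bda.find(f"{_NS}binary")
    raw = base64.b64decode(node.text or "")
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> Run:
    """Load centroided mzML into a :class:`Run`.

    Parses the standard spectrum/cvParam/binaryDataArray layout (64- or
    32-bit, optionally zlib-compressed arrays) with stdlib XML; handles the
    subset of the format that :func:`write_mzml` and common converters emit
    for centroided data.
    """
    import xml.etree.ElementTree as ET

    tree = ET.parse(str(path))
    scans: List[Scan] = []
    for spec in tree.iter(f"{_NS}spectrum"):
        cv = {c.get("accession"): c.get("value") for c in spec.iter(f"{_NS}cvParam")}
        level = int(cv.get(_ACC_MS_LEVEL, 1))
        rt = float(cv.get(_ACC_SCAN_START, "nan"))
        prec = float(cv[_ACC_SELECTED_MZ]) if _ACC_SELECTED_MZ in cv else None
        mz = intensity = None
        for bda in spec.iter(f"{_NS}binaryDataArray"):
            accs = {c.get("accession") for c in bda.iter(f"{_NS}cvParam")}
            data = _decode_binary(bda)
            if _ACC_MZ_ARRAY in accs:
                mz = data
            elif _ACC_INTENSITY_ARRAY in accs:
                intensity = data
        if mz is None or intensity is None:
            raise ValueError(f"spectrum {spec.get('id')!r} lacks m/z or intensity array")
        scans.append(
            Scan(
                level=level,
                rt_min=rt,
                mz=mz,
                intensity=intensity,
                precursor_mz=prec,
                isolation_width=1.0 if level == 2 else None,
            )
        )
    return Run(scans=scans)


# ---------------------------------------------------------------------------
# default study conditions

def default_mixture() -> MixtureSpec:
    """Asynchronous-cell-like mixture: K4 methylation coupled to acetyl degree.

    Abundance falls steeply with acetyl degree (poly-acetylated tails are a
    small fraction of total H3) while the K4 methyl stoichiometry shifts
    toward me2/me3 as the degree rises, so trimethylation is essentially
    confined to hyperacetylated proteoforms.
    """
    return MixtureSpec(
        abundances={0: 100.0, 1: 30.0, 2: 10.0, 3: 3.0, 4: 1.0, 5: 0.3},
        k4={
            0: (0.960, 0.030, 0.008, 0.002),
            1: (0.900, 0.070, 0.025, 0.005),
            2: (0.800, 0.130, 0.055, 0.015),
            3: (0.600, 0.250, 0.110, 0.040),
            4: (0.400, 0.300, 0.200, 0.100),
            5: (0.200, 0.300, 0.250, 0.250),
        },
    )


def default_trajectory() -> List[Tuple[float, MixtureSpec]]:
    """KDAC-inhibition time course (0-120 min): hyperacetylation accumulates
    and me3 within the 5ac class rises monotonically."""
    times = (0.0, 10.0, 20.0, 30.0, 60.0, 120.0)
    base = default_mixture()
    out = []
    for i, t in enumerate(times):
        w = i / (len(times) - 1)
        ab = {
            a: float(v * (1.0 + w * (a - 1.0)))  # high degrees gain, 0ac loses
            if a >= 1
            else float(v * (1.0 - 0.6 * w))
            for a, v in base.abundances.items()
        }
        k4 = {}
        for a, pi in base.k4.items():
            me3 = pi[3] * (1.0 + 2.0 * w * a / 5.0)
            rest = 1.0 - me3
            scale = rest / (pi[0] + pi[1] + pi[2])
            k4[a] = (pi[0] * scale, pi[1] * scale, pi[2] * scale, me3)
        out.append((t, MixtureSpec(ab, k4)))
    return out
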