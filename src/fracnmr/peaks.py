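"""CB/CA ratio statistics and stereospecific methyl calls from peak lists.

The intra-residue Cβ/Cα peak-height ratio from an HNCACB-type spectrum is an
amino-acid-type signature under fractional 13C labeling.  This module turns
assigned peak lists into per-residue ratio records (with explicit exclusion
reasons), aggregates them per residue type, scores them against the
isotopomer model's predicted bands and calls pro-R/pro-S methyl assignments
from constant-time HSQC multiplet annotations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from . import isotopomer as iso
from .errors import ExcludedResidueError, InputError

__all__ = [
    "Peak",
    "RatioRecord",
    "MethylPeak",
    "detect_overlap",
    "compute_cbca_ratios",
    "aggregate_by_type",
    "infer_type_group",
    "stereo_assign_methyls",
    "DEFAULT_OVERLAP_TOL",
]

# The paper-era convention for HSQC/triple-resonance axes; the paper only
# states that overlapped signals were removed, so tolerances are ours.
DEFAULT_OVERLAP_TOL = {"H": 0.03, "N": 0.3, "C": 0.3}

#: peak roles in a CA/CB triple-resonance experiment
ROLE_CA_I = "CA_i"
ROLE_CB_I = "CB_i"
ROLE_CA_IM1 = "CA_i-1"
ROLE_CB_IM1 = "CB_i-1"

EXCL_NONE = "none"
EXCL_GLY = "glycine"
EXCL_PRO = "proline"
EXCL_OVERLAP = "overlap"
EXCL_MISSING = "missing-peak"


@dataclass(frozen=True)
class Peak:
    """One assigned peak of a 2D/3D spectrum."""

    residue_number: int
    residue_type: str
    atoms: tuple[str, ...]
    dims: tuple[float, ...]
    intensity: float
    role: str | None = None
    overlap: bool = False

    def __post_init__(self):
        if not math.isfinite(self.intensity):
            raise InputError(
                f"peak {self.residue_type}{self.residue_number}: non-finite intensity"
            )
        if len(self.atoms) != len(self.dims):
            raise InputError(
                f"peak {self.residue_type}{self.residue_number}: "
                f"{len(self.atoms)} atoms vs {len(self.dims)} shifts"
            )


@dataclass(frozen=True)
class MethylPeak:
    """A ct-HSQC methyl peak with its multiplet annotation."""

    residue_number: int
    residue_type: str
    atom: str
    multiplet: str  # "singlet" | "doublet"


@dataclass(frozen=True)
class RatioRecord:
    residue_number: int
    residue_type: str
    ratio: float | None = None
    excluded: str = EXCL_NONE

    def __post_init__(self):
        if (self.ratio is None) != (self.excluded != EXCL_NONE):
            raise ValueError("ratio present iff excluded == 'none'")


def detect_overlap(peaks: list[Peak], tol_ppm=None) -> list[Peak]:
    """Flag every pair of peaks lying within tolerance on ALL axes.

    ``tol_ppm`` is either a mapping from nucleus letter (H/N/C) to ppm or a
    sequence of per-axis tolerances; defaults to
    :data:`DEFAULT_OVERLAP_TOL`.  Returns new peaks; both members of an
    overlapping pair are flagged.
    """
    def tols(p: Peak):
        if tol_ppm is None or isinstance(tol_ppm, dict):
            table = DEFAULT_OVERLAP_TOL if tol_ppm is None else tol_ppm
            return [table[a[0]] for a in p.atoms]
        return list(tol_ppm)

    for t in (tols(p) for p in peaks[:1]):
        if any(x <= 0 for x in t):
            raise InputError("overlap tolerances must be positive")

    flagged = [False] * len(peaks)
    for i in range(len(peaks)):
        ti = tols(peaks[i])
        for j in range(i + 1, len(peaks)):
            if len(peaks[j].dims) != len(peaks[i].dims):
                continue
            if all(
                abs(a - b) < t
                for a, b, t in zip(peaks[i].dims, peaks[j].dims, ti)
            ):
                flagged[i] = flagged[j] = True
    return [
        replace(p, overlap=True) if f and not p.overlap else p
        for p, f in zip(peaks, flagged)
    ]


def compute_cbca_ratios(peaks: list[Peak], use_abs: bool = True) -> list[RatioRecord]:
    """Per-residue intra-residue CB/CA peak intensity ratios.

    Every residue present in the input appears exactly once in the output,
    either with a ratio or with an exclusion reason (glycine, proline,
    overlap, missing-peak).  Sequential (i-1) peaks are accepted in the
    input but never used.  ``use_abs`` takes absolute intensities, for
    experiments in which Cβ peaks invert sign.
    """
    by_res: dict[int, dict] = {}
    for p in peaks:
        entry = by_res.setdefault(
            p.residue_number, {"type": p.residue_type, "peaks": {}}
        )
        if entry["type"] != p.residue_type:
            raise InputError(
                f"residue {p.residue_number}: conflicting types "
                f"{entry['type']} vs {p.residue_type}"
            )
        if p.role in (ROLE_CA_I, ROLE_CB_I):
            if p.role in entry["peaks"] and not (
                p.overlap or entry["peaks"][p.role].overlap
            ):
                raise InputError(
                    f"residue {p.residue_number}: duplicate {p.role} peak "
                    "without overlap flag"
                )
            entry["peaks"][p.role] = p

    records = []
    for resnum in sorted(by_res):
        rtype = by_res[resnum]["type"].upper()
        rpeaks = by_res[resnum]["peaks"]
        if rtype in ("GLY", "G"):
            records.append(RatioRecord(resnum, rtype, None, EXCL_GLY))
            continue
        if rtype in ("PRO", "P"):
            records.append(RatioRecord(resnum, rtype, None, EXCL_PRO))
            continue
        ca, cb = rpeaks.get(ROLE_CA_I), rpeaks.get(ROLE_CB_I)
        if ca is None or cb is None:
            records.append(RatioRecord(resnum, rtype, None, EXCL_MISSING))
            continue
        if ca.overlap or cb.overlap:
            records.append(RatioRecord(resnum, rtype, None, EXCL_OVERLAP))
            continue
        ia, ib = ca.intensity, cb.intensity
        if use_abs:
            ia, ib = abs(ia), abs(ib)
        if ia == 0:
            records.append(RatioRecord(resnum, rtype, None, EXCL_MISSING))
            continue
        records.append(RatioRecord(resnum, rtype, ib / ia))
    return records


def aggregate_by_type(records: list[RatioRecord]) -> pd.DataFrame:
    """Mean, sd and count of CB/CA ratios per residue type.

    Excluded records are not counted.  Raises on empty input or when every
    record is excluded.
    """
    rows = [
        (r.residue_type.upper(), r.ratio)
        for r in records
        if r.excluded == EXCL_NONE
    ]
    if not rows:
        raise InputError("no unexcluded ratio records to aggregate")
    df = pd.DataFrame(rows, columns=["residue_type", "ratio"])
    out = df.groupby("residue_type")["ratio"].agg(["mean", "std", "count"])
    return out.rename(columns={"std": "sd", "count": "n"})


def _default_bands(scheme=None, attenuation=None):
    scheme = scheme or iso.LabelingScheme(0.2)
    bands = {}
    for group in (iso.GROUP_INTACT, iso.GROUP_TCA, iso.GROUP_BROKEN):
        ratios = [
            iso.predict_cbca_ratio(aa, scheme, attenuation)
            for aa in iso.STANDARD_RESIDUES
            if aa not in ("GLY", "PRO") and iso.classify_group(aa) == group
        ]
        bands[group] = (min(ratios), max(ratios))
    return bands


def infer_type_group(
    ratio: float,
    scheme: iso.LabelingScheme | None = None,
    attenuation=None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> list[tuple[str, float]]:
    """Rank amino-acid-type groups for an observed CB/CA ratio.

    Each group's band is the span of model-predicted ratios of its members
    (default scheme f=0.2 with calibrated attenuation).  A ratio inside a
    band scores 1; outside, the score decays with distance in units of the
    band width.  Result is sorted by descending score with a deterministic
    tie-break in the order intact-high, intermediate-TCA, broken-low.
    """
    if ratio < 0:
        raise InputError("ratio must be non-negative")
    if bands is None:
        bands = _default_bands(scheme, attenuation)
    order = [iso.GROUP_INTACT, iso.GROUP_TCA, iso.GROUP_BROKEN]
    scored = []
    for group in order:
        lo, hi = bands[group]
        # scale: at least the band width, but never below 10% of the band
        # level, so single-member bands still have a sensible basin
        scale = max(hi - lo, 0.1 * hi, 1e-3)
        dist = max(lo - ratio, ratio - hi, 0.0)
        scored.append((group, 1.0 / (1.0 + dist / scale)))
    scored.sort(key=lambda gs: (-gs[1], order.index(gs[0])))
    return scored


def stereo_assign_methyls(
    methyl_peaks: list[MethylPeak],
) -> dict[int, dict[str, str] | None]:
    """pro-R/pro-S calls for Val/Leu methyl pairs from multiplet patterns.

    A doublet methyl is pro-R (intact bond to its precursor neighbor), a
    singlet is pro-S.  Residues whose two methyls carry the same annotation
    are returned as ``None`` with a warning.  Each residue must contribute
    exactly two methyl records.
    """
    by_res: dict[int, list[MethylPeak]] = {}
    for m in methyl_peaks:
        aa = m.residue_type.upper()
        if aa not in ("VAL", "LEU", "V", "L"):
            raise ExcludedResidueError(
                f"residue {m.residue_number} ({m.residue_type}): "
                "no diastereotopic methyls"
            )
        if m.multiplet not in ("singlet", "doublet"):
            raise InputError(f"unknown multiplet annotation {m.multiplet!r}")
        by_res.setdefault(m.residue_number, []).append(m)

    out: dict[int, dict[str, str] | None] = {}
    for resnum, pair in sorted(by_res.items()):
        if len(pair) != 2:
            raise InputError(
                f"residue {resnum}: expected exactly 2 methyl peaks, got {len(pair)}"
            )
        a, b = pair
        if a.multiplet == b.multiplet:
            warnings.warn(
                f"residue {resnum}: both methyls are {a.multiplet}s; "
                "stereo assignment left open"
            )
            out[resnum] = None
            continue
        out[resnum] = {
            m.atom: ("pro-R" if m.multiplet == "doublet" else "pro-S")
            for m in pair
        }
    return out
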