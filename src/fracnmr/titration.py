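"""Chemical-shift-perturbation analysis of HSQC titration series.

CSPs are combined 1H/15N amide shift changes,
``d_av = sqrt(dH^2 + (0.154*dN)^2)``, computed endpoint-versus-reference
over a series of ligand:protein molar ratios; residues with ``d_av``
strictly above a threshold (default 0.01 ppm) are called significant.
Side-chain NH peaks (Trp indole, Asn/Gln amides) ride along as
pseudo-residues with a string suffix on the residue id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "TitrationSeries",
    "CSPRecord",
    "csp",
    "track_peaks",
    "compute_csp_records",
    "call_significant",
    "N_WEIGHT",
]

#: weight of the 15N axis relative to 1H in the combined shift
N_WEIGHT = 0.154


def csp(delta_h: float, delta_n: float) -> float:
    """Combined amide chemical shift perturbation (ppm)."""
    if not (math.isfinite(delta_h) and math.isfinite(delta_n)):
        raise InputError("shift differences must be finite")
    return math.sqrt(delta_h ** 2 + (N_WEIGHT * delta_n) ** 2)


@dataclass(frozen=True)
class CSPRecord:
    residue: int | str
    delta_h: float
    delta_n: float
    delta_av: float
    significant: bool


class TitrationSeries:
    """Ordered titration points: (molar ratio, peak table).

    Each peak table maps residue id to (dH ppm, dN ppm); pandas DataFrames
    with columns residue/dH_ppm/dN_ppm are accepted too.  The first point
    must be the ligand-free reference (ratio 0).
    """

    def __init__(self, points, protein_conc_mM: float | None = None):
        parsed = []
        for ratio, table in points:
            if isinstance(table, pd.DataFrame):
                table = {
                    row["residue"]: (float(row["dH_ppm"]), float(row["dN_ppm"]))
                    for _, row in table.iterrows()
                }
            parsed.append((float(ratio), dict(table)))
        if not parsed:
            raise InputError("titration series is empty")
        ratios = [r for r, _ in parsed]
        if ratios[0] != 0.0:
            raise InputError("first titration point must be the 0:1 reference")
        if any(b <= a for a, b in zip(ratios, ratios[1:])) or any(r < 0 for r in ratios):
            raise InputError("molar ratios must be non-negative and strictly increasing")
        self.points = parsed
        self.protein_conc_mM = protein_conc_mM

    @property
    def ratios(self) -> list[float]:
        return [r for r, _ in self.points]

    @property
    def reference(self) -> dict:
        return self.points[0][1]

    @property
    def endpoint(self) -> dict:
        return self.points[-1][1]


def _match_unassigned(reference: dict, observed_positions, tol: float):
    """Nearest-neighbor match in scaled (dH, 0.154*dN) space.

    Returns residue -> (dH, dN) for unambiguous matches; residues whose
    nearest observed peak is claimed by another reference peak within
    tolerance are flagged ambiguous (both of them), never silently assigned.
    """
    obs = list(observed_positions)
    matched, claims = {}, {}
    for res, (h0, n0) in reference.items():
        best, best_d = None, tol
        for k, (h, n) in enumerate(obs):
            d = math.hypot(h - h0, N_WEIGHT * (n - n0))
            if d <= best_d:
                best, best_d = k, d
        if best is not None:
            claims.setdefault(best, []).append(res)
    ambiguous = set()
    for k, residues in claims.items():
        if len(residues) > 1:
            ambiguous.update(residues)
        else:
            matched[residues[0]] = obs[k]
    return matched, ambiguous


def track_peaks(series: TitrationSeries, tolerance: float = 0.05) -> pd.DataFrame:
    """Per-residue shift trajectories across the titration.

    Later points that carry assignments are joined on the residue id;
    unassigned points (tables keyed by integer position rather than by a
    reference residue) fall back to nearest-neighbor matching within
    ``tolerance`` in the scaled shift space.  Output is a long-format frame
    with columns residue, ratio, dH_ppm, dN_ppm, status
    (ok/unmatched/ambiguous).
    """
    ref = series.reference
    rows = []
    for ratio, table in series.points:
        assigned = set(table) & set(ref)
        if assigned:
            for res in ref:
                if res in table:
                    h, n = table[res]
                    rows.append((res, ratio, h, n, "ok"))
                else:
                    rows.append((res, ratio, math.nan, math.nan, "unmatched"))
        else:
            matched, ambiguous = _match_unassigned(ref, table.values(), tolerance)
            for res in ref:
                if res in ambiguous:
                    rows.append((res, ratio, math.nan, math.nan, "ambiguous"))
                elif res in matched:
                    h, n = matched[res]
                    rows.append((res, ratio, h, n, "ok"))
                else:
                    rows.append((res, ratio, math.nan, math.nan, "unmatched"))
    return pd.DataFrame(
        rows, columns=["residue", "ratio", "dH_ppm", "dN_ppm", "status"]
    )


def compute_csp_records(
    series: TitrationSeries, threshold: float = 0.01
) -> list[CSPRecord]:
    """Endpoint-vs-reference CSP for every residue of the reference point."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    ref, end = series.reference, series.endpoint
    records = []
    for res in sorted(ref, key=str):
        if res not in end:
            continue
        dh = end[res][0] - ref[res][0]
        dn = end[res][1] - ref[res][1]
        d_av = csp(dh, dn)
        records.append(CSPRecord(res, dh, dn, d_av, d_av > threshold))
    return records


def call_significant(
    records: list[CSPRecord], threshold: float = 0.01
) -> list[CSPRecord]:
    """Residues with d_av strictly above the threshold (default 0.01 ppm)."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    return [
        CSPRecord(r.residue, r.delta_h, r.delta_n, r.delta_av, True)
        for r in records
        if r.delta_av > threshold
    ]


def bound_fraction(ratio: float, protein_mM: float, kd_mM: float) -> float:
    """Exact 1:1 binding quadratic: fraction of protein bound at a molar ratio."""
    p0, l0 = protein_mM, ratio * protein_mM
    s = p0 + l0 + kd_mM
    return (s - math.sqrt(s * s - 4.0 * p0 * l0)) / (2.0 * p0)
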