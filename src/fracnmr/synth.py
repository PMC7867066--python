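"""Seeded generators for every input type the analysis modules consume.

Every generator returns machine-readable truth alongside its data so that
analysis results can be checked against the generating parameters.  All
randomness flows from one integer seed; each generator draws from its own
substream, so identical configs give bit-identical output regardless of
call order.  Intensity noise is multiplicative log-normal; shift and
coordinate noise is additive Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import isotopomer as iso
from .peaks import Peak
from .structure import Conformer
from .titration import N_WEIGHT, bound_fraction

__all__ = [
    "GeneratorConfig",
    "gen_peaklist",
    "gen_decay",
    "gen_titration",
    "gen_ensemble",
    "T1_DELAYS_MS",
    "T2_DELAYS_MS",
]

# delay series of the reference experiment setup
T1_DELAYS_MS = (10.0, 50.0, 100.0, 200.0, 300.0, 500.0, 800.0, 1000.0, 1200.0, 2000.0)
T2_DELAYS_MS = (16.0, 64.0, 96.0, 128.0, 156.0, 196.0, 224.0, 256.0)

TITRATION_RATIOS = (0.0, 0.25, 1.0, 5.0, 12.5, 25.0)

_STREAMS = {"peaks": 1, "decay": 2, "titration": 3, "ensemble": 4}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_residues: int = 80
    composition: dict[str, int] | None = None  # residue type -> count
    scheme: iso.LabelingScheme = field(default_factory=lambda: iso.LabelingScheme(0.2))
    attenuation: object = None  # passed through to predict_cbca_ratio

    # peak list
    peak_noise: float = 0.05          # log-normal sigma on intensities
    base_intensity: float = 1000.0

    # relaxation
    t1_ms: float = 694.0
    t2_ms: float = 104.0
    t_spread: float = 0.0             # relative sd of per-residue true T
    decay_noise: float = 0.02         # Gaussian sd relative to I0

    # titration
    protein_mM: float = 0.73
    kd_mM: float = 5.0
    n_perturbed: int = 4
    delta_max_ppm: float = 0.05
    jitter_ppm: float = 0.001

    # ensemble
    n_models: int = 20
    ensemble_sigma: float = 0.5       # per-coordinate Gaussian sd, Angstrom
    n_ens_residues: int = 30

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def _residue_sequence(config: GeneratorConfig) -> list[tuple[int, str]]:
    """Deterministic residue-number/type sequence from the composition."""
    if config.composition:
        seq = [aa.upper() for aa, k in sorted(config.composition.items())
               for _ in range(k)]
    else:
        cycle = list(iso.STANDARD_RESIDUES)
        seq = [cycle[i % len(cycle)] for i in range(config.n_residues)]
    return [(i + 1, aa) for i, aa in enumerate(seq)]


def gen_peaklist(config: GeneratorConfig):
    """Synthetic assigned HNCACB-style intra-residue peak list.

    CA_i peaks get a log-normal intensity around ``base_intensity``; CB_i
    intensities are CA_i times the isotopomer model's predicted CB/CA
    ratio, with independent multiplicative noise.  Gly rows lack a CB peak
    and Pro rows are absent entirely (no amide).  Returns
    ``(peaks, truth)`` where truth lists the generating ratio per residue.
    """
    rng = config.rng("peaks")
    peaks: list[Peak] = []
    truth_rows = []
    for resnum, aa in _residue_sequence(config):
        if aa == "PRO":
            truth_rows.append((resnum, aa, math.nan))
            continue
        h = rng.uniform(7.0, 9.5)
        n = rng.uniform(105.0, 130.0)
        ca = rng.uniform(45.0, 65.0)
        i_ca = config.base_intensity * rng.lognormal(0.0, config.peak_noise)
        peaks.append(Peak(resnum, aa, ("H", "N", "CA"), (h, n, ca), i_ca,
                          role="CA_i"))
        if aa == "GLY":
            truth_rows.append((resnum, aa, math.nan))
            continue
        ratio = iso.predict_cbca_ratio(aa, config.scheme, config.attenuation)
        cb = rng.uniform(18.0, 45.0)
        i_cb = i_ca * ratio * rng.lognormal(0.0, config.peak_noise)
        peaks.append(Peak(resnum, aa, ("H", "N", "CB"), (h, n, cb), i_cb,
                          role="CB_i"))
        truth_rows.append((resnum, aa, ratio))
    truth = pd.DataFrame(truth_rows, columns=["residue", "residue_type", "true_ratio"])
    return peaks, truth


def gen_decay(config: GeneratorConfig):
    """Synthetic T1/T2 relaxation series at the standard delay lists.

    Returns ``(data, truth)``: a long-format frame with columns residue,
    experiment, delay_ms, intensity and a truth frame with the generating
    time constants.
    """
    rng = config.rng("decay")
    rows, truth_rows = [], []
    for resnum, _ in _residue_sequence(config):
        for exp, t_true, delays in (("T1", config.t1_ms, T1_DELAYS_MS),
                                    ("T2", config.t2_ms, T2_DELAYS_MS)):
            t_res = t_true * (1.0 + config.t_spread * rng.standard_normal()) \
                if config.t_spread > 0 else t_true
            i0 = config.base_intensity
            for d in delays:
                val = i0 * math.exp(-d / t_res)
                if config.decay_noise > 0:
                    val += config.decay_noise * i0 * rng.standard_normal()
                rows.append((resnum, exp, d, val))
            truth_rows.append((resnum, exp, t_res, i0))
    data = pd.DataFrame(rows, columns=["residue", "experiment", "delay_ms", "intensity"])
    truth = pd.DataFrame(truth_rows, columns=["residue", "experiment", "true_T_ms", "I0"])
    return data, truth


def gen_titration(config: GeneratorConfig):
    """Fast-exchange two-state titration over the standard molar ratios.

    Perturbed residues move along a fixed per-residue direction by
    ``bound_fraction * delta_max``; all residues get additive Gaussian
    jitter.  Returns ``(points, truth)`` where points is a list of
    ``(ratio, {residue: (dH, dN)})`` suitable for
    :class:`fracnmr.titration.TitrationSeries`.
    """
    rng = config.rng("titration")
    residues = [r for r, aa in _residue_sequence(config) if aa != "PRO"]
    free = {r: (rng.uniform(7.0, 9.5), rng.uniform(105.0, 130.0)) for r in residues}
    perturbed = list(rng.choice(residues, size=config.n_perturbed, replace=False))
    directions = {}
    for r in perturbed:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        # direction normalized so the full-saturation CSP equals delta_max
        directions[r] = (config.delta_max_ppm * math.cos(theta),
                         config.delta_max_ppm * math.sin(theta) / N_WEIGHT)

    points = []
    for ratio in TITRATION_RATIOS:
        fb = bound_fraction(ratio, config.protein_mM, config.kd_mM) if ratio > 0 else 0.0
        table = {}
        for r in residues:
            h, n = free[r]
            if r in directions:
                h += fb * directions[r][0]
                n += fb * directions[r][1]
            if config.jitter_ppm > 0 and ratio > 0:
                h += config.jitter_ppm * rng.standard_normal()
                n += (config.jitter_ppm / N_WEIGHT) * rng.standard_normal()
            table[r] = (h, n)
        points.append((ratio, table))

    sat = bound_fraction(TITRATION_RATIOS[-1], config.protein_mM, config.kd_mM)
    truth = pd.DataFrame(
        [(r, r in directions,
          sat * config.delta_max_ppm if r in directions else 0.0)
         for r in residues],
        columns=["residue", "perturbed", "expected_csp"],
    )
    return points, truth


def _base_fold(n_residues: int) -> Conformer:
    """Toy helical chain with N, CA, C, O, CB per residue."""
    rise, turn, radius = 1.5, math.radians(100.0), 2.3
    res_nums, res_types, atom_names, coords = [], [], [], []
    offsets = {"N": (-0.6, -0.8, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (0.9, 0.6, 0.2), "O": (1.2, 1.6, 0.2),
               "CB": (-0.5, 0.8, 1.2)}
    for i in range(n_residues):
        ang = i * turn
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), rise * i])
        for atom, off in offsets.items():
            res_nums.append(i + 1)
            res_types.append("ALA")
            atom_names.append(atom)
            coords.append(ca + np.array(off))
    return Conformer(np.array(res_nums), np.array(res_types, dtype=object),
                     np.array(atom_names, dtype=object), np.array(coords))


def gen_ensemble(config: GeneratorConfig):
    """Multi-model bundle: base fold + per-model Gaussian noise + rigid motion.

    Returns ``(models, truth)`` with truth carrying the base conformer and
    the generating sigma.
    """
    rng = config.rng("ensemble")
    base = _base_fold(config.n_ens_residues)
    models = []
    for m in range(config.n_models):
        coords = base.coords + config.ensemble_sigma * rng.standard_normal(
            base.coords.shape
        )
        # random proper rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1.0
        shift = rng.uniform(-20.0, 20.0, size=3)
        models.append(Conformer(
            base.residue_numbers.copy(), base.residue_types.copy(),
            base.atom_names.copy(), coords @ q.T + shift, model_id=m + 1,
        ))
    truth = {"sigma": config.ensemble_sigma, "base": base}
    return models, truth
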