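"""Synthetic peak-list generation for end-to-end pipeline testing.

No peak coordinates from the underlying spectra are deposited anywhere,
so every pipeline stage is exercised on synthetic data: paired HSQC lists
with controlled, localized perturbations plus Gaussian noise (emulating a
free/ligand-bound titration point), and SLF lists drawn from the PISA
forward model at stated tilt/rotation with per-axis noise (emulating a
SAMMY spectrum of a tilted TM helix, or a superposition of two wheels for
the dimer).

Unperturbed HSQC base positions are drawn once per residue from uniform
windows (¹H 7.5-9.0 ppm, ¹⁵N 105-130 ppm) seeded by the residue index, so
they are stable across runs; spectral realism beyond peak geometry is
irrelevant to what these lists test.  Residue 1 and prolines carry no
backbone amide H-N pair and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .construct import Construct
from .csp import HNPeak
from .helix_model import HelixGeometry
from .oriented_nmr import BicelleModel, CSATensor, SLFPeak, WheelParams, pisa_wheel

__all__ = ["SynthSpec", "amide_residues", "gen_hsqc_pair", "gen_slf", "gen_dimer_slf"]

_H_WINDOW = (7.5, 9.0)
_N_WINDOW = (105.0, 130.0)


@dataclass(frozen=True)
class SynthSpec:
    """Noise and perturbation settings for the generators.

    ``perturbations`` maps construct residue → (ΔδH, ΔδN) in ppm, added to
    the bound list only.  Noise standard deviations are Gaussian, per axis,
    independent between free and bound.
    """

    seed: int = 0
    noise_h: float = 0.0
    noise_n: float = 0.0
    noise_shift: float = 0.0
    noise_coupling: float = 0.0
    perturbations: Mapping[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("noise_h", "noise_n", "noise_shift", "noise_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def amide_residues(c: Construct) -> list[int]:
    """Construct positions carrying a backbone amide H-N pair.

    Excludes residue 1 (free amine) and prolines (no amide proton).
    """
    return [i for i, aa in c.residues() if i > 1 and aa != "P"]


def _base_shifts(residue: int) -> tuple[float, float]:
    # per-residue rng: base positions depend only on the residue index
    rng = np.random.default_rng(residue)
    h = rng.uniform(*_H_WINDOW)
    n = rng.uniform(*_N_WINDOW)
    return h, n


def gen_hsqc_pair(c: Construct, spec: SynthSpec
                  ) -> tuple[list[HNPeak], list[HNPeak]]:
    """Paired free/bound HSQC peak lists with injected perturbations.

    One peak per amide-bearing residue.  The bound list is the free base
    positions plus the stated per-residue perturbations; both lists then
    receive independent Gaussian noise.  Identical specs (same seed)
    produce identical output.
    """
    residues = amide_residues(c)
    for r in spec.perturbations:
        if r not in residues:
            raise ValueError(
                f"perturbation on residue {r}, which has no backbone amide "
                "(residue 1 or proline) or is outside the construct"
            )
    rng = np.random.default_rng(spec.seed)
    free, bound = [], []
    for r in residues:
        h0, n0 = _base_shifts(r)
        eh_f, en_f, eh_b, en_b = rng.normal(size=4)
        dh, dn = spec.perturbations.get(r, (0.0, 0.0))
        free.append(HNPeak(h_ppm=h0 + spec.noise_h * eh_f,
                           n_ppm=n0 + spec.noise_n * en_f, residue=r))
        bound.append(HNPeak(h_ppm=h0 + dh + spec.noise_h * eh_b,
                            n_ppm=n0 + dn + spec.noise_n * en_b, residue=r))
    return free, bound


def gen_slf(h: HelixGeometry, t15n: CSATensor, w: WheelParams,
            b: BicelleModel, spec: SynthSpec,
            residues: list[int] | None = None,
            keep_labels: bool = True) -> list[SLFPeak]:
    """SLF peak list from the PISA forward model plus per-axis noise.

    With zero noise the output equals :func:`pisa_wheel` exactly.  Noise
    is added to the observed coordinates; the coupling axis stores the
    magnitude, so a noise excursion through zero folds back positive.
    """
    clean = pisa_wheel(h, t15n, w, b, residues=residues)
    rng = np.random.default_rng(spec.seed)
    out = []
    for p in clean:
        es, ec = rng.normal(size=2)
        out.append(SLFPeak(
            shift_ppm=p.shift_ppm + spec.noise_shift * es,
            coupling_khz=abs(p.coupling_khz + spec.noise_coupling * ec),
            residue=p.residue if keep_labels else None,
            coupling_sign=p.coupling_sign,
        ))
    return out


def gen_dimer_slf(h: HelixGeometry, t15n: CSATensor,
                  w_a: WheelParams, w_b: WheelParams, b: BicelleModel,
                  spec: SynthSpec,
                  residues_a: list[int] | None = None,
                  residues_b: list[int] | None = None,
                  keep_labels: bool = True,
                  component_labels: bool = False
                  ) -> list[SLFPeak] | tuple[list[SLFPeak], list[int]]:
    """Superposition of two PISA wheels, emulating a dimer of
    inequivalent monomers (e.g. tilts 6° and 16°).

    Residue spans may be disjoint or identical.  With
    ``component_labels=True`` also returns the component index (0/1) of
    each peak, for recovery scoring.
    """
    spec_a = SynthSpec(seed=spec.seed, noise_shift=spec.noise_shift,
                       noise_coupling=spec.noise_coupling)
    spec_b = SynthSpec(seed=spec.seed + 1, noise_shift=spec.noise_shift,
                       noise_coupling=spec.noise_coupling)
    pa = gen_slf(h, t15n, w_a, b, spec_a, residues=residues_a,
                 keep_labels=keep_labels)
    pb = gen_slf(h, t15n, w_b, b, spec_b, residues=residues_b,
                 keep_labels=keep_labels)
    peaks = pa + pb
    if component_labels:
        return peaks, [0] * len(pa) + [1] * len(pb)
    return peaks
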