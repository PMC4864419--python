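"""Synthetic inputs with the statistical structure each analysis stage
assumes, so the full pipeline runs and is testable fully offline.

* NOE tables: ISPA-consistent volumes V = V_ref (d_ref / d)^6 from the
  actual inter-proton distances of a template structure, with
  multiplicative lognormal integration noise (default 10%).
* Coupling sets: forward Karplus prediction from the template's own sugar
  puckers, with additive Gaussian noise (default 0.5 Hz).
* Ensembles: coordinate-jittered copies of a template emulating an NMR
  conformer bundle (default 20 models, 0.04 A isotropic jitter, giving a
  mean pairwise backbone RMSD near 0.1 A; model 1 is the unperturbed
  template).  Jitter is uncorrelated per atom — cruder than a real
  restrained-MD bundle but sufficient for RMSD and distance statistics.
* DSC traces: the two-state bimolecular model of :mod:`.melting` at the
  study's melting parameters.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .coupling import CouplingSet, KarplusParams, KARPLUS_HH, predict_sugar_couplings
from .duplex import Ensemble, StructureModel
from .ensemble import pucker_from_coords
from .melting import DEFAULT_CT, DscCurve, simulate_dsc_curve
from .restraints import REFERENCE_DISTANCE, NoePeak

__all__ = ["SynthConfig", "synth_noe_table", "synth_couplings", "synth_ensemble", "synth_dsc"]

#: exchangeable (imino/amino) protons never observed in D2O NOESY
EXCHANGEABLE_PROTONS = frozenset(
    {"H1", "H21", "H22", "H3", "H41", "H42", "H61", "H62"}
)
#: geminal proton pairs (fixed distances, excluded from NOE restraints)
_GEMINAL = (
    {"H2'", "H2''"},
    {"H5'", "H5''"},
    {"H21", "H22"},
    {"H41", "H42"},
    {"H61", "H62"},
)
#: thymine methyl protons (degenerate group, left out of the peak table)
_METHYL = frozenset({"H71", "H72", "H73"})


@dataclass
class SynthConfig:
    """Knobs of the synthetic-data generators (defaults = study conditions)."""

    seed: int = 0
    noe_cutoff: float = 6.0  # A, NOESY observability horizon
    reference_volume: float = 1000.0  # arbitrary volume units for H5-H6
    volume_noise: float = 0.10  # lognormal sigma (fractional)
    coupling_noise_hz: float = 0.5
    ensemble_size: int = 20
    jitter_sd: float = 0.04  # A per coordinate: 20-model bundle ~ 0.1 A pairwise RMSD
    tm_c: float = 76.55
    dh: float = 300.0
    ct: float = DEFAULT_CT
    dsc_noise_frac: float = 0.02  # of peak height

    def __post_init__(self):
        if self.noe_cutoff > 8.0:
            raise ValueError("NOE cutoff beyond 8 A is not observable")
        for name in ("volume_noise", "coupling_noise_hz", "jitter_sd", "dsc_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _is_geminal(res_a, name_a, res_b, name_b) -> bool:
    if res_a != res_b:
        return False
    return any(name_a in g and name_b in g for g in _GEMINAL)


def synth_noe_table(model: StructureModel, cfg: SynthConfig) -> List[NoePeak]:
    """ISPA-consistent NOESY peak table from a template's proton distances.

    Every proton pair closer than the cutoff yields one peak with volume
    V_ref (d_ref / d)^6 times lognormal noise.  Geminal pairs and thymine
    methyl protons are excluded; peaks involving exchangeable protons are
    flagged and carry an intensity class assigned from the true distance
    (strong <= 3.0 A, medium <= 4.2 A, else weak) as a stand-in for the
    mixing-time classification of water NOESY data.
    """
    protons = [a for a in model.atoms if a.element == "H" and a.name not in _METHYL]
    if not protons:
        raise ValueError("model has no hydrogens")
    rng = cfg.rng(stream=1)
    coords = np.array([a.coord for a in protons])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    peaks = []
    n = len(protons)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > cfg.noe_cutoff:
                continue
            a, b = protons[i], protons[j]
            if _is_geminal(a.res_num, a.name, b.res_num, b.name):
                continue
            noise = float(np.exp(rng.normal(0.0, cfg.volume_noise))) if cfg.volume_noise else 1.0
            vol = cfg.reference_volume * (REFERENCE_DISTANCE / d[i, j]) ** 6 * noise
            exch = a.name in EXCHANGEABLE_PROTONS or b.name in EXCHANGEABLE_PROTONS
            cls = None
            if exch:
                cls = "strong" if d[i, j] <= 3.0 else ("medium" if d[i, j] <= 4.2 else "weak")
            peaks.append(
                NoePeak(
                    a.res_num, a.name, b.res_num, b.name,
                    volume=vol, mixing_time_ms=150.0,
                    exchangeable=exch, intensity=cls,
                )
            )
    return peaks


def synth_couplings(
    model: StructureModel,
    cfg: SynthConfig,
    params: KarplusParams = KARPLUS_HH,
) -> Dict[int, CouplingSet]:
    """Per-residue sugar H-H couplings predicted from the template's own
    ring coordinates, plus Gaussian measurement noise."""
    rng = cfg.rng(stream=2)
    out = {}
    for res in model.residue_numbers():
        pucker, _ = pucker_from_coords(model, res)
        cs = predict_sugar_couplings(pucker, params)
        if cfg.coupling_noise_hz > 0:
            noisy = {}
            for name, _ in cs.hh_items():
                v = getattr(cs, name) + rng.normal(0.0, cfg.coupling_noise_hz)
                noisy[name] = float(np.clip(v, 0.0, 25.0))
            cs = CouplingSet(**noisy)
        out[res] = cs
    return out


def synth_ensemble(model: StructureModel, cfg: SynthConfig) -> Ensemble:
    """Jittered-copy conformer bundle; model 1 is the unperturbed template."""
    if cfg.ensemble_size < 2:
        raise ValueError("ensemble needs at least 2 models")
    rng = cfg.rng(stream=3)
    coords = model.coords()
    models = [model.with_coords(coords, model_index=1)]
    for k in range(2, cfg.ensemble_size + 1):
        jit = rng.normal(0.0, cfg.jitter_sd, size=coords.shape) if cfg.jitter_sd else 0.0
        models.append(model.with_coords(coords + jit, model_index=k))
    return Ensemble(models, label=f"synthetic(jitter={cfg.jitter_sd})")


def synth_dsc(cfg: SynthConfig, tm_c: Optional[float] = None, dh: Optional[float] = None) -> DscCurve:
    """Two-state DSC trace at the configured melting parameters."""
    tm_c = cfg.tm_c if tm_c is None else tm_c
    dh = cfg.dh if dh is None else dh
    clean = simulate_dsc_curve(tm_c, dh, cfg.ct)
    noise_sd = cfg.dsc_noise_frac * float(clean.dcp.max())
    if noise_sd == 0:
        return clean
    return simulate_dsc_curve(
        tm_c, dh, cfg.ct, noise_sd=noise_sd, seed=int(cfg.rng(stream=4).integers(2**31))
    )
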