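"""Deterministic synthetic datasets for offline testing and fitting demos.

Everything here is generated by running the package's own engines with a
fixed seed — no external downloads.  Route fixtures (including the
reconstructed Alpe d'Huez profile) live in :mod:`endurosim.routes`; this
module adds biopsy-style creatine-kinase datasets that emulate the
structure of incremental-exercise muscle measurements: ATP, PCr and Cr
concentrations per workload, in mmol per kg dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from endurosim.ck import (
    CKParams,
    ProtonState,
    convert_concentration,
    load_default_params,
    steady_state_constant_forcing,
    workload_to_flux,
)

__all__ = ["SyntheticCKDataSpec", "generate_ck_dataset"]

#: [H+] interpolation anchors: 0.89e-7 M at rest rising to 1.20e-7 M at 75 %
_H_REST, _H_75 = 0.89e-7, 1.20e-7


def proton_for_fraction(fraction: float) -> ProtonState:
    """Workload-dependent [H+], linear between the rest and 75 % anchors."""
    h = _H_REST + (_H_75 - _H_REST) * fraction / 0.75
    return ProtonState(h)


@dataclass(frozen=True)
class SyntheticCKDataSpec:
    """Recipe for a reproducible synthetic biopsy dataset."""

    workload_fractions: tuple[float, ...] = (0.40, 0.75)
    noise_sd_rel: float = 0.02
    seed: int = 7
    vo2max_l_per_min: float = 4.1
    muscle_mass_kg: float = 10.0
    params: CKParams | None = None

    def __post_init__(self) -> None:
        if len(self.workload_fractions) < 2:
            raise ValueError("need at least two workload fractions")
        if self.noise_sd_rel < 0:
            raise ValueError("noise sd must be >= 0")


def generate_ck_dataset(spec: SyntheticCKDataSpec) -> pd.DataFrame:
    """Simulated steady-state biopsy concentrations with multiplicative noise.

    For each workload fraction the model is driven to its steady state at
    the corresponding average hydrolysis flux, the volume-weighted ATP, PCr
    and Cr concentrations are converted to mmol/kg dry weight, and
    multiplicative Gaussian noise at ``noise_sd_rel`` is applied with the
    fixed seed.  ``noise_sd_rel = 0`` returns the model outputs exactly.
    """
    p = spec.params or load_default_params()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for frac in spec.workload_fractions:
        j = workload_to_flux(spec.vo2max_l_per_min, frac, spec.muscle_mass_kg)
        h = proton_for_fraction(frac)
        st = steady_state_constant_forcing(p, j, h)
        mixed = p.v_cyt * st.cytosol + p.v_ims * st.ims
        for name, idx in (("ATP", 0), ("PCr", 2), ("Cr", 3)):
            value = convert_concentration(mixed[idx] / 1e3, "mmol_per_kg_dw")
            noisy = value * (1.0 + spec.noise_sd_rel * rng.standard_normal())
            rows.append(
                (f"w{int(round(frac * 100))}", name, noisy,
                 max(spec.noise_sd_rel, 1e-3) * value, j, h.h_molar)
            )
    return pd.DataFrame(
        rows,
        columns=["condition", "metabolite", "value_mmol_per_kg_dw", "sd",
                 "j_avg_uM_per_s", "h_molar"],
    )
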