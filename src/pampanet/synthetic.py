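"""Synthetic descriptor/permeability datasets with known ground truth.

The generator emulates the data regime of a curated PAMPA permeability
table: a descriptor matrix with a block of strongly inter-correlated
columns (pairwise correlation above 0.8), a handful of zero-variance
columns, many uninformative noise columns, and logPe values spanning
roughly −8.5…−4.5 with about half the molecules on each side of the
−6.2 permeability cutoff.  The signal driving logPe combines a linear
term, one pairwise interaction and one saturating nonlinearity over the
informative descriptors, so a flexible nonlinear model can beat a linear
baseline on it.  Full bookkeeping (informative names, coefficients,
noise-free signal and the noise draws) is returned, which makes the
Bayes-optimal R² computable for any generated dataset.

Raw PAMPA plate measurements can also be synthesised by inverting the
permeability equation (:func:`generate_pampa_measurements`), giving
donor/acceptor concentrations that reproduce a requested logPe exactly.

What this generator does not emulate: real molecules (descriptor columns
are opaque Gaussian features, not chemistry), descriptor-engine
artefacts, assay replicates or pH effects.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .chemdata import DescriptorTable
from .pampa import PampaMeasurement, membrane_retention

__all__ = [
    "SyntheticSpec",
    "generate_descriptor_dataset",
    "generate_pampa_measurements",
    "default_instrument",
    "add_output_noise",
]

# inner-bracket admissibility window keeping the logPe round trip stable to <1e-9
_INNER_MIN = 1e-6
_INNER_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise structure of one synthetic dataset."""

    n_molecules: int = 190
    n_descriptors: int = 60
    n_informative: int = 5
    n_constant: int = 5
    correlated_block_size: int = 8
    block_correlation: float = 0.9
    noise_sd: float = 0.15
    logpe_center: float = -6.2
    logpe_spread: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_constant + self.correlated_block_size > self.n_descriptors:
            raise ValueError("informative + constant + correlated columns exceed n_descriptors")
        if not 0 < self.block_correlation < 1:
            raise ValueError("block_correlation must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_molecules < 2 or self.n_informative < 0:
            raise ValueError("infeasible spec")


def generate_descriptor_dataset(spec: SyntheticSpec):
    """Generate ``(DescriptorTable, logPe array, ground_truth dict)``.

    Ground truth records the informative descriptor names and their
    coefficients, the noise-free signal, the noise draws and the Bayes
    R² = var(signal)/(var(signal)+noise_sd²) achievable by any model.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_molecules, spec.n_descriptors

    n_inf = spec.n_informative
    informative = rng.standard_normal((n, n_inf))

    # signal: linear + one interaction + one saturating term
    coefs = np.linspace(1.0, 0.4, num=max(n_inf, 1))[:n_inf]
    signal = informative @ coefs if n_inf else np.zeros(n)
    if n_inf >= 2:
        signal = signal + 0.5 * informative[:, 0] * informative[:, 1]
    if n_inf >= 3:
        signal = signal + 0.8 * np.tanh(2.0 * informative[:, 2])
    if n_inf and signal.std() > 0:
        signal = (signal - signal.mean()) / signal.std()

    noise = rng.standard_normal(n) * spec.noise_sd
    log_pe = spec.logpe_center + spec.logpe_spread * signal + noise

    # correlated block: common latent factor + independent residuals
    rho = spec.block_correlation
    latent = rng.standard_normal((n, 1))
    block = math.sqrt(rho) * latent + math.sqrt(1 - rho) * rng.standard_normal(
        (n, spec.correlated_block_size)
    )

    n_noise = p - n_inf - spec.n_constant - spec.correlated_block_size
    noise_cols = rng.standard_normal((n, n_noise))
    const_cols = np.zeros((n, spec.n_constant))

    names = (
        [f"inf_{i+1}" for i in range(n_inf)]
        + [f"blk_{i+1}" for i in range(spec.correlated_block_size)]
        + [f"const_{i+1}" for i in range(spec.n_constant)]
        + [f"noise_{i+1}" for i in range(n_noise)]
    )
    values = np.hstack([informative, block, const_cols, noise_cols])
    table = DescriptorTable(
        pd.DataFrame(values, index=[f"synth_{i+1}" for i in range(n)], columns=names),
        backend=f"synthetic (seed={spec.seed})",
    )
    signal_var = float(np.var(spec.logpe_spread * signal))
    ground_truth = {
        "spec": asdict(spec),
        "informative_names": names[:n_inf],
        "constant_names": [f"const_{i+1}" for i in range(spec.n_constant)],
        "block_names": [f"blk_{i+1}" for i in range(spec.correlated_block_size)],
        "linear_coefficients": coefs.tolist(),
        "signal": (spec.logpe_center + spec.logpe_spread * signal).tolist(),
        "noise": noise.tolist(),
        "bayes_r2": signal_var / (signal_var + spec.noise_sd**2)
        if signal_var + spec.noise_sd**2 > 0
        else 0.0,
    }
    return table, log_pe, ground_truth


def default_instrument() -> PampaMeasurement:
    """Typical 96-well PAMPA settings: 0.3 cm³ wells, 0.3 cm², 4 h, porosity 1.

    The concentration fields are placeholders; the generator overwrites
    them per requested logPe.
    """
    return PampaMeasurement(
        v_donor=0.3, v_acceptor=0.3, area=0.3, t=14400.0, tau_ss=0.0,
        epsilon_a=1.0, c_donor_0=1.0, c_acceptor_t=0.01, c_donor_t=0.9,
    )


def generate_pampa_measurements(
    log_pe_values, instrument: PampaMeasurement | None = None, retention: float = 0.0
):
    """Invert the permeability equation: concentrations reproducing each logPe.

    For every requested logPe the acceptor concentration ratio is solved
    from the permeability equation and the donor concentration from the
    retention formula at the requested R_M, so that feeding the
    measurement back through ``effective_log_permeability`` recovers the
    input.  Raises for logPe values too fast or too slow for the
    instrument settings (inner bracket outside the admissible window).
    """
    inst = instrument or default_instrument()
    if not 0.0 <= retention < 1.0:
        raise ValueError("retention must lie in [0, 1)")
    r_v = inst.r_v
    out = []
    for lp in np.atleast_1d(np.asarray(log_pe_values, dtype=float)):
        pe = 10.0**lp
        log_inner = -pe * inst.area * (inst.t - inst.tau_ss) * inst.epsilon_a * (1 + r_v) / (
            2.303 * inst.v_donor
        )
        inner = 10.0**log_inner
        if not _INNER_MIN <= inner <= _INNER_MAX:
            raise ValueError(
                f"logPe {lp:.3g} inadmissible for these instrument settings "
                f"(inner bracket {inner:.3g})"
            )
        ca_ratio = (1.0 - inner) * (1.0 - retention) / (1.0 + 1.0 / r_v)
        cd_ratio = 1.0 - retention + (inst.v_acceptor / inst.v_donor) * ca_ratio
        m = PampaMeasurement(
            v_donor=inst.v_donor,
            v_acceptor=inst.v_acceptor,
            area=inst.area,
            t=inst.t,
            tau_ss=inst.tau_ss,
            epsilon_a=inst.epsilon_a,
            c_donor_0=inst.c_donor_0,
            c_acceptor_t=ca_ratio * inst.c_donor_0,
            c_donor_t=cd_ratio * inst.c_donor_0,
        )
        assert abs(membrane_retention(m) - retention) < 1e-12
        out.append(m)
    return out


def add_output_noise(log_pe_values, noise_sd: float, seed: int = 0) -> np.ndarray:
    """Seeded Gaussian perturbation of measured logPe (noise-robustness studies)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    values = np.asarray(log_pe_values, dtype=float)
    if noise_sd == 0:
        return values.copy()
    rng = np.random.default_rng(seed)
    return values + rng.standard_normal(values.shape) * noise_sd
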