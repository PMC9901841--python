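"""PAMPA raw-measurement conversion to effective permeability (logPe).

The parallel artificial membrane permeability assay measures passive
diffusion of a compound from a donor to an acceptor compartment across a
lipid-infused filter.  From the donor/acceptor concentrations after an
incubation of length ``t`` the effective permeability coefficient
``Pe`` (cm/s) is obtained as

    Pe = −(2.303·V_D) / (A·(t − τ_ss)·ε_a) · 1/(1 + r_v)
         · log10[ 1 − ((1 + r_v⁻¹)/(1 − R_M)) · C_A(t)/C_D(0) ]

with ``r_v = V_D/V_A`` and the membrane retention ratio

    R_M = 1 − ( C_D(t)/C_D(0) − V_A·C_A(t)/(V_D·C_D(0)) ).

All lengths are cm, volumes cm³, times s; concentrations only enter as
ratios, so any consistent unit is accepted.  Permeability is modelled on
the log10 scale (``logPe``); at pH 7.4 a rough classification puts
compounds with logPe ≥ −6.2 in the "higher permeability" class.

The printed R_M formula above differs from a strict mass-balance
derivation (which subtracts, rather than adds back, the acceptor term);
``membrane_retention`` follows the printed form by default and exposes
the mass-balance form behind ``convention="mass_balance"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PampaMeasurement",
    "NoPermeationError",
    "InadmissibleMeasurementError",
    "membrane_retention",
    "effective_log_permeability",
    "classify_permeability",
    "count_permeability_classes",
    "PERMEABILITY_CUTOFF",
]

#: logPe classification cutoff at pH 7.4; the boundary itself is "higher".
PERMEABILITY_CUTOFF = -6.2


class NoPermeationError(ValueError):
    """No detectable compound in the acceptor well: Pe = 0, logPe undefined."""


class InadmissibleMeasurementError(ValueError):
    """Measurement outside the validity range of the permeability equation."""


@dataclass(frozen=True)
class PampaMeasurement:
    """Raw quantities from one PAMPA well.

    Parameters
    ----------
    v_donor, v_acceptor : float
        Compartment volumes, cm³.
    area : float
        Membrane area, cm².
    t : float
        Incubation time, s.
    tau_ss : float
        Lag time to steady state, s.
    epsilon_a : float
        Apparent membrane porosity (dimensionless, > 0).
    c_donor_0 : float
        Initial donor concentration.
    c_acceptor_t, c_donor_t : float
        Acceptor and donor concentrations at time ``t`` (same units as
        ``c_donor_0``).
    """

    v_donor: float
    v_acceptor: float
    area: float
    t: float
    tau_ss: float
    epsilon_a: float
    c_donor_0: float
    c_acceptor_t: float
    c_donor_t: float

    def __post_init__(self):
        for name in ("v_donor", "v_acceptor", "area", "epsilon_a", "c_donor_0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.t > self.tau_ss:
            raise ValueError("experiment time t must exceed the lag time tau_ss")
        if self.c_acceptor_t < 0 or self.c_donor_t < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def r_v(self) -> float:
        """Donor/acceptor volume ratio V_D/V_A (derived, never stored)."""
        return self.v_donor / self.v_acceptor


def membrane_retention(m: PampaMeasurement, convention: str = "printed") -> float:
    """Membrane retention ratio R_M.

    ``convention="printed"`` (default) evaluates
    ``1 − (C_D(t)/C_D(0) − V_A·C_A(t)/(V_D·C_D(0)))``;
    ``convention="mass_balance"`` evaluates
    ``1 − C_D(t)/C_D(0) − V_A·C_A(t)/(V_D·C_D(0))``.
    """
    donor_frac = m.c_donor_t / m.c_donor_0
    acceptor_term = (m.v_acceptor * m.c_acceptor_t) / (m.v_donor * m.c_donor_0)
    if convention == "printed":
        return 1.0 - (donor_frac - acceptor_term)
    if convention == "mass_balance":
        return 1.0 - donor_frac - acceptor_term
    raise ValueError(f"unknown R_M convention {convention!r}")


def effective_log_permeability(
    m: PampaMeasurement, retention: float | None = None
) -> float:
    """log10 of the effective permeability coefficient Pe (cm/s).

    ``retention`` overrides the R_M computed from the measurement, which
    is convenient when the donor concentration at ``t`` was not read.

    Raises
    ------
    NoPermeationError
        If ``C_A(t) = 0`` (the inner bracket is 1 and Pe = 0).
    InadmissibleMeasurementError
        If R_M ≥ 1 or the inner bracket falls outside (0, 1), i.e. the
        transport ran beyond the range where the equation is valid.
    """
    if m.c_acceptor_t == 0:
        raise NoPermeationError("no detectable permeation: C_A(t) = 0")
    r_m = membrane_retention(m) if retention is None else retention
    if r_m >= 1.0:
        raise InadmissibleMeasurementError(f"membrane retention R_M = {r_m:.4g} >= 1")
    r_v = m.r_v
    inner = 1.0 - ((1.0 + 1.0 / r_v) / (1.0 - r_m)) * (m.c_acceptor_t / m.c_donor_0)
    if not 0.0 < inner < 1.0:
        raise InadmissibleMeasurementError(
            f"inner bracket {inner:.4g} outside (0, 1): transport beyond the "
            "validity of the permeability equation"
        )
    prefactor = -(2.303 * m.v_donor) / (m.area * (m.t - m.tau_ss) * m.epsilon_a)
    pe = prefactor * (1.0 / (1.0 + r_v)) * math.log10(inner)
    return math.log10(pe)


def classify_permeability(log_pe: float, cutoff: float = PERMEABILITY_CUTOFF) -> str:
    """Classify a logPe value as ``"higher"`` (logPe ≥ cutoff) or ``"lower"``."""
    if not math.isfinite(log_pe):
        raise ValueError("logPe must be finite")
    return "higher" if log_pe >= cutoff else "lower"


def count_permeability_classes(records, cutoff: float = PERMEABILITY_CUTOFF):
    """Count (n_higher, n_lower) over molecule records carrying observed logPe."""
    n_higher = n_lower = 0
    for rec in records:
        log_pe = rec.log_pe if hasattr(rec, "log_pe") else float(rec)
        if log_pe is None:
            raise ValueError(f"record {getattr(rec, 'id', rec)!r} has no observed logPe")
        if classify_permeability(log_pe, cutoff) == "higher":
            n_higher += 1
        else:
            n_lower += 1
    return n_higher, n_lower
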