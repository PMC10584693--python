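"""Minimal limiting-factor model of mtDNA homeostasis.

The concentration of mitochondrial DNA, ``n``, evolves under three
processes: replication catalysed by the mtDNA polymerase Mip1 (cellular
concentration ``m``), degradation counteracted stoichiometrically by the
packaging factor Abf2 (concentration ``a``), and dilution by exponential
cell growth with doubling time ``T``::

    dn/dt = kR * m / (K1 + m/n)  -  kD * n / (K2 + a/n)  -  n * ln2 / T

Both the replication and degradation terms depend on the protein
concentrations only through the ratios ``m/n`` and ``a/n``.  The model
family ``dn/dt = n*f(m/n) - n*g(a/n) - n*ln2/T`` is therefore homogeneous:
scaling ``m`` and ``a`` by a common factor scales the steady state by the
same factor.  If the *amounts* of Mip1 and Abf2 grow in proportion to cell
volume (constant concentrations), the steady-state mtDNA concentration is
volume-independent, i.e. mtDNA copy number scales linearly with volume.

Setting ``dn/dt = 0`` and discarding the trivial root ``n = 0`` leaves a
quadratic ``A*n**2 + B*n + C = 0`` whose unique positive root (when it
exists, equivalent to ``kR*T > ln2``) is the steady state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "SteadyState",
    "DosagePerturbation",
    "WILD_TYPE_GRID",
    "rate",
    "steady_state_coefficients",
    "steady_state",
    "relative_mtdna",
    "integrate",
    "sweep",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and concentrations of the homeostasis model.

    Parameters are in mutually consistent arbitrary units (one unit for
    concentrations, one for time); the model is qualitative by design.

    kR : maximal replication rate constant (1/time)
    kD : degradation rate constant (1/time)
    K1 : Mip1–mtDNA dissociation constant (concentration)
    K2 : degradation saturation constant (concentration)
    T  : population doubling time (time)
    m  : Mip1 concentration
    a  : Abf2 concentration
    """

    kR: float
    kD: float
    K1: float
    K2: float
    T: float
    m: float
    a: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"ModelParams.{name} must be finite and > 0, got {value!r}")

    def scaled(self, fm: float = 1.0, fa: float = 1.0) -> "ModelParams":
        """Return a copy with Mip1 and Abf2 concentrations multiplied by fm, fa."""
        return replace(self, m=self.m * fm, a=self.a * fa)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls(**json.loads(Path(path).read_text()))


#: The four wild-type parameter sets explored for gene-dosage predictions:
#: m=5, a=100, T=150, K1=5, K2=100, with kR in {0.01, 0.1} x kD in {1, 10}.
WILD_TYPE_GRID: tuple[ModelParams, ...] = tuple(
    ModelParams(kR=kR, kD=kD, K1=5.0, K2=100.0, T=150.0, m=5.0, a=100.0)
    for kR in (0.01, 0.1)
    for kD in (1.0, 10.0)
)


@dataclass(frozen=True)
class SteadyState:
    """Steady-state mtDNA concentration; exists=False means only n=0 is stable."""

    n: float
    exists: bool

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("steady-state concentration must be non-negative")
        if not self.exists and self.n != 0:
            raise ValueError("nonexistent steady state must have n = 0")


@dataclass(frozen=True)
class DosagePerturbation:
    """Multiplicative gene-dosage factors on Mip1 (fm) and Abf2 (fa).

    A single hemizygote is (0.5, 1) or (1, 0.5); the double hemizygote is
    (0.5, 0.5); twofold joint overexpression is (2, 2).
    """

    fm: float
    fa: float

    def __post_init__(self) -> None:
        if not (self.fm > 0 and self.fa > 0):
            raise ValueError("dosage factors must be > 0")


def rate(n: float, p: ModelParams) -> float:
    """Time derivative dn/dt of the mtDNA concentration.

    At ``n = 0`` both saturable terms are defined by their limits (0), so 0
    is always a fixed point.
    """
    if n < 0:
        raise ValueError(f"mtDNA concentration must be >= 0, got {n}")
    if n == 0:
        return 0.0
    replication = p.kR * p.m / (p.K1 + p.m / n)
    degradation = p.kD * n / (p.K2 + p.a / n)
    dilution = n * _LN2 / p.T
    return replication - degradation - dilution


def steady_state_coefficients(p: ModelParams) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of the steady-state quadratic A n² + B n + C = 0.

    Obtained by clearing denominators in ``rate(n, p)/n = 0``:

        A = K1*K2*ln2 + kD*K1*T
        B = a*K1*ln2 - K2*m*kR*T + K2*m*ln2 + kD*m*T
        C = a*m*ln2 - a*m*kR*T

    A is always positive; a strictly positive root exists iff C < 0,
    i.e. iff kR*T > ln2.
    """
    A = p.K1 * p.K2 * _LN2 + p.kD * p.K1 * p.T
    B = p.a * p.K1 * _LN2 - p.K2 * p.m * p.kR * p.T + p.K2 * p.m * _LN2 + p.kD * p.m * p.T
    C = p.a * p.m * _LN2 - p.a * p.m * p.kR * p.T
    return A, B, C


def steady_state(p: ModelParams) -> SteadyState:
    """Solve for the steady-state mtDNA concentration.

    Returns the unique strictly positive root of the quadratic when it
    exists (C < 0 guarantees exactly one, since the root product C/A is then
    negative), else ``SteadyState(0, exists=False)``.
    """
    A, B, C = steady_state_coefficients(p)
    if C >= 0:
        return SteadyState(0.0, False)
    # Numerically stable quadratic formula (avoid cancellation in -B + sqrt).
    disc = math.sqrt(B * B - 4.0 * A * C)
    if B >= 0:
        n = (2.0 * -C) / (B + disc)
    else:
        n = (-B + disc) / (2.0 * A)
    return SteadyState(n, True)


def relative_mtdna(p: ModelParams, d: DosagePerturbation) -> float:
    """Steady-state mtDNA of a dosage-perturbed strain relative to wild type.

    The double hemizygote (fm = fa = 0.5) gives exactly 0.5 for any valid
    parameter set, by homogeneity; single hemizygotes land between 0.5 and
    1.0 depending on which of replication and degradation is closer to
    saturation.
    """
    wt = steady_state(p)
    if not wt.exists:
        raise ValueError("wild-type steady state does not exist for these parameters")
    return steady_state(p.scaled(d.fm, d.fa)).n / wt.n


def integrate(
    p: ModelParams,
    n0: float,
    t_end: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the rate equation from n0 over [0, t_end].

    Explicit RK4 with fixed step dt and a non-negativity clamp; the scalar
    ODE is non-stiff for any positive parameter set.  Serves as the
    independent dynamic route to the steady state (the quadratic root being
    the algebraic route).

    Returns (times, values).
    """
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be > 0")
    n_steps = int(math.ceil(t_end / dt))
    times = np.empty(n_steps + 1)
    values = np.empty(n_steps + 1)
    times[0], values[0] = 0.0, n0
    n = float(n0)
    for i in range(1, n_steps + 1):
        h = min(dt, t_end - times[i - 1])
        k1 = rate(n, p)
        k2 = rate(max(n + 0.5 * h * k1, 0.0), p)
        k3 = rate(max(n + 0.5 * h * k2, 0.0), p)
        k4 = rate(max(n + h * k3, 0.0), p)
        n = n + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(n):
            raise ArithmeticError(
                "integration diverged to a non-finite value; reduce dt"
            )
        n = max(n, 0.0)
        times[i] = times[i - 1] + h
        values[i] = n
    return times, values


def sweep(
    p_grid: Sequence[ModelParams] | Iterable[ModelParams],
    perturbations: Sequence[DosagePerturbation] | Iterable[DosagePerturbation],
) -> pd.DataFrame:
    """Relative steady-state mtDNA for every (parameter set, perturbation) pair.

    Returns a DataFrame with columns params_id, kR, kD, fm, fa,
    relative_mtdna; params_id indexes the grid order.
    """
    rows = []
    perturbations = list(perturbations)
    for i, p in enumerate(p_grid):
        for d in perturbations:
            rows.append(
                {
                    "params_id": i,
                    "kR": p.kR,
                    "kD": p.kD,
                    "fm": d.fm,
                    "fa": d.fa,
                    "relative_mtdna": relative_mtdna(p, d),
                }
            )
    return pd.DataFrame(
        rows, columns=["params_id", "kR", "kD", "fm", "fa", "relative_mtdna"]
    )
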