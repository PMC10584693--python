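"""Absolute mtDNA copy-number quantification from qPCR plates.

The calculus: per-primer standard curves (Cq linear in log10 template
concentration) convert pooled technical-replicate Cq values to DNA
concentrations; nuclear-gene (ACT1, MIP1, MRX6) and mitochondrial-gene
(COX2, COX3) concentrations are averaged into one nDNA and one mtDNA
concentration; their ratio gives mtDNA copies per nDNA.  The budding index
of the sampled population converts that ratio to copies per cell — an
unbudded haploid carries 1 nuclear genome and a budded one 2 (diploids 2
and 4), so the mean nDNA content per cell is a linear interpolation in the
fraction of budded cells.  Dividing by the population mean cell volume
yields copies per fL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NUCLEAR_GENES",
    "MITO_GENES",
    "StandardCurve",
    "PopulationRecord",
    "CopyNumberResult",
    "pool_technical_replicates",
    "fit_standard_curve",
    "cq_to_concentration",
    "concentration_to_cq",
    "pool_gene_groups",
    "ndna_per_cell",
    "copy_number",
    "normalize_to_reference",
    "quantify_plate",
]

NUCLEAR_GENES = ("ACT1", "MIP1", "MRX6")
MITO_GENES = ("COX2", "COX3")


@dataclass(frozen=True)
class StandardCurve:
    """Per-primer calibration line: Cq = slope * log10(conc) + intercept.

    slope is negative (more template amplifies earlier); efficiency
    E = 10**(-1/slope) - 1 equals 1.0 for perfect doubling chemistry.
    """

    gene: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (self.slope < 0):
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class PopulationRecord:
    """Population-level context for one sample."""

    sample: str
    mean_volume_fl: float
    budding_index_pct: float
    ploidy: str  # "haploid" | "diploid"

    def __post_init__(self) -> None:
        if self.mean_volume_fl <= 0:
            raise ValueError("mean_volume_fl must be > 0")
        if not (0 <= self.budding_index_pct <= 100):
            raise ValueError("budding_index_pct must be in [0, 100]")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError("ploidy must be 'haploid' or 'diploid'")


@dataclass(frozen=True)
class CopyNumberResult:
    """mtDNA copy number on the three scales the scaling analyses use."""

    sample: str
    mt_per_ndna: float
    ndna_per_cell: float
    mt_per_cell: float
    mt_per_fl: float


def pool_technical_replicates(
    cqs: Sequence[float], sd_max: float = 0.5, iterate: bool = False
) -> tuple[float, list[int]]:
    """Mean Cq of technical replicates with the s.d.-based outlier rule.

    If the sample s.d. exceeds ``sd_max``, the replicate farthest from the
    median is excluded and the remainder re-tested (once by default;
    ``iterate=True`` repeats until the s.d. passes or two replicates
    remain).  Returns (mean Cq, indices of excluded replicates);
    mean is NaN if the well fails (s.d. still too high).
    """
    values = np.asarray(cqs, dtype=float)
    if values.size == 0:
        raise ValueError("at least one replicate required")
    if not np.all(np.isfinite(values) & (values > 0)):
        raise ValueError("Cq values must be finite and positive")
    idx = list(range(values.size))
    excluded: list[int] = []
    while True:
        sub = values[idx]
        if sub.size < 2 or sub.std(ddof=1) <= sd_max:
            return float(sub.mean()), excluded
        can_drop = len(idx) > 2 and (iterate or not excluded)
        if not can_drop:
            return float("nan"), excluded  # failed well
        far = int(np.argmax(np.abs(sub - np.median(sub))))
        excluded.append(idx.pop(far))


def fit_standard_curve(
    concentrations: Sequence[float], cqs: Sequence[float], gene: str = ""
) -> StandardCurve:
    """Ordinary least squares of Cq against log10(concentration in pg/µL)."""
    conc = np.asarray(concentrations, dtype=float)
    cq = np.asarray(cqs, dtype=float)
    if conc.size != cq.size or conc.size < 2:
        raise ValueError("need >= 2 (concentration, Cq) pairs")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    res = stats.linregress(np.log10(conc), cq)
    return StandardCurve(gene=gene, slope=float(res.slope), intercept=float(res.intercept))


def cq_to_concentration(cq: float, curve: StandardCurve) -> float:
    """Template concentration (pg/µL) implied by a Cq on the curve."""
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def concentration_to_cq(conc: float, curve: StandardCurve) -> float:
    """Inverse of :func:`cq_to_concentration`."""
    if conc <= 0:
        raise ValueError("concentration must be > 0")
    return curve.slope * math.log10(conc) + curve.intercept


def pool_gene_groups(
    concentrations: Mapping[str, float],
    nuclear: Iterable[str] = NUCLEAR_GENES,
    mito: Iterable[str] = MITO_GENES,
    exclude: Iterable[str] = (),
) -> tuple[float, float]:
    """Mean nuclear and mitochondrial DNA concentrations.

    ``exclude`` removes genes from pooling (e.g. MIP1 in strains whose MIP1
    copy number was manipulated).  Missing (NaN) genes are skipped.
    """
    excluded = set(exclude)

    def _pool(genes: Iterable[str]) -> float:
        vals = [
            concentrations[g]
            for g in genes
            if g in concentrations and g not in excluded and np.isfinite(concentrations[g])
        ]
        if not vals:
            raise ValueError("no usable genes left in group after exclusions")
        return float(np.mean(vals))

    return _pool(nuclear), _pool(mito)


def ndna_per_cell(budding_index_pct: float, ploidy: str) -> float:
    """Average nuclear genome copies per cell from the budding index.

    haploid: (%buds*2 + %no-buds*1)/100;  diploid: (%buds*4 + %no-buds*2)/100.
    """
    b = budding_index_pct
    if not (0 <= b <= 100):
        raise ValueError("budding index must be in [0, 100]")
    if ploidy == "haploid":
        return (b * 2.0 + (100.0 - b) * 1.0) / 100.0
    if ploidy == "diploid":
        return (b * 4.0 + (100.0 - b) * 2.0) / 100.0
    raise ValueError("ploidy must be 'haploid' or 'diploid'")


def copy_number(mt_per_ndna: float, pop: PopulationRecord) -> CopyNumberResult:
    """Copies per nDNA -> copies per cell -> copies per fL for one sample."""
    if mt_per_ndna < 0:
        raise ValueError("mt_per_ndna must be >= 0")
    npc = ndna_per_cell(pop.budding_index_pct, pop.ploidy)
    mt_cell = mt_per_ndna * npc
    return CopyNumberResult(
        sample=pop.sample,
        mt_per_ndna=mt_per_ndna,
        ndna_per_cell=npc,
        mt_per_cell=mt_cell,
        mt_per_fl=mt_cell / pop.mean_volume_fl,
    )


def normalize_to_reference(
    values: Mapping[str, float] | pd.Series, reference: str
) -> pd.Series:
    """Divide per-strain values by the reference strain's value."""
    s = pd.Series(values, dtype=float)
    if reference not in s.index:
        raise ValueError(f"reference strain {reference!r} missing")
    ref = s[reference]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("reference value is zero or missing")
    return s / ref


# ---------------------------------------------------------------------------
# table-level driver


def quantify_plate(
    plate: pd.DataFrame,
    standards: pd.DataFrame,
    populations: pd.DataFrame,
    sd_max: float = 0.5,
    exclude_genes: Iterable[str] = (),
    nuclear: Iterable[str] = NUCLEAR_GENES,
    mito: Iterable[str] = MITO_GENES,
) -> pd.DataFrame:
    """Full plate-to-copy-number pipeline over CSV-shaped tables.

    plate : columns sample, gene, replicate, cq.
    standards : columns gene, concentration_pg_per_ul, cq.
    populations : columns sample, mean_volume_fl, budding_index_pct, ploidy.

    Returns one row per sample with the CopyNumberResult fields; failed
    wells propagate as NaN, never as zero.
    """
    curves = {
        gene: fit_standard_curve(
            grp["concentration_pg_per_ul"].to_numpy(), grp["cq"].to_numpy(), gene
        )
        for gene, grp in standards.groupby("gene")
    }
    rows = []
    pops = {r.sample: PopulationRecord(r.sample, r.mean_volume_fl,
                                       r.budding_index_pct, r.ploidy)
            for r in populations.itertuples(index=False)}
    for sample, sample_grp in plate.groupby("sample"):
        conc: dict[str, float] = {}
        for gene, gene_grp in sample_grp.groupby("gene"):
            mean_cq, _ = pool_technical_replicates(gene_grp["cq"].to_numpy(), sd_max)
            if math.isnan(mean_cq):
                conc[gene] = float("nan")
            else:
                conc[gene] = cq_to_concentration(mean_cq, curves[gene])
        n_conc, mt_conc = pool_gene_groups(conc, nuclear, mito, exclude_genes)
        res = copy_number(mt_conc / n_conc, pops[sample])
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
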