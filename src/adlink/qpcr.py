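"""qPCR quantification and estimated absolute abundance (EAA).

Total 16S rRNA gene copies measured by qPCR anchor the sequencing data to an
absolute scale.  The chain is:

1. a standard curve fit (Cq vs log10 copies per reaction) converts mean Cq
   to copies per µL of DNA template;
2. the normalized copy number ``N = copies/µL × V_t / V_S`` expresses total
   16S copies per mL of reactor sample (V_t µL eluted template from V_S mL
   of sample);
3. estimated absolute abundance per genus is ``EAA = N × RA`` where RA is
   the genus' relative abundance among all sequences of that sample.

Relative abundance for EAA is computed on NON-rarefied counts; rarefaction
(without replacement, to a fixed depth) is provided separately for the
ordination and diversity statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountTable, FormatError

log = logging.getLogger("adlink")

#: Assay detection limit, 16S gene copies per mL of reactor sample.
DETECTION_LIMIT_COPIES_PER_ML = 1.6e5

#: Volume of DNA template in one qPCR reaction (µL).
TEMPLATE_UL_PER_REACTION = 1.0


class InsufficientDataError(ValueError):
    """Too few dilution levels to fit a standard curve."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(copies per reaction).

    ``efficiency`` is the per-cycle amplification efficiency
    ``10**(-1/slope) - 1``; 1.0 means perfect doubling each cycle
    (slope -log2(10) ≈ -3.3219).
    """

    slope: float
    intercept: float
    r_squared: float
    flagged: bool = False

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class QpcrResult:
    sample_id: str
    cq_values: list[float]
    mean_cq: float
    copies_per_ul_template: float
    below_detection: bool = False


@dataclass
class AbundanceTable:
    """Per-sample estimated absolute abundance (molecules/mL of sample).

    ``eaa`` and ``ra`` are taxa × samples DataFrames; ``n`` is the
    per-sample total copy concentration N.  Columns of ``eaa`` sum to N by
    construction.
    """

    eaa: pd.DataFrame
    ra: pd.DataFrame
    n: pd.Series

    @property
    def taxa(self) -> list[str]:
        return list(self.eaa.index)

    @property
    def samples(self) -> list[str]:
        return list(self.eaa.columns)


def fit_standard_curve(dilution_points: list[tuple[float, float]]) -> StandardCurve:
    """Fit Cq = slope * log10(copies) + intercept by ordinary least squares.

    Parameters
    ----------
    dilution_points
        (log10 copies per reaction, Cq) pairs from a serial dilution.
    """
    if len({round(x, 12) for x, _ in dilution_points}) < 3:
        raise InsufficientDataError(
            "standard curve needs >= 3 distinct dilution levels"
        )
    x = np.array([p[0] for p in dilution_points], dtype=float)
    y = np.array([p[1] for p in dilution_points], dtype=float)
    fit = stats.linregress(x, y)
    flagged = fit.slope >= 0
    if flagged:
        log.warning("standard curve has nonnegative slope %.4f; flagged", fit.slope)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        flagged=flagged,
    )


def quantify_copies(
    mean_cq: float,
    curve: StandardCurve,
    template_ul_per_reaction: float = TEMPLATE_UL_PER_REACTION,
) -> float:
    """Copies per µL of template from a mean Cq via the standard curve.

    The curve gives copies per reaction; division by the template volume per
    reaction converts to per-µL.
    """
    copies_per_reaction = 10.0 ** ((mean_cq - curve.intercept) / curve.slope)
    return copies_per_reaction / template_ul_per_reaction


def normalized_copy_number(copies_per_ul_template: float, v_t: float, v_s: float) -> float:
    """Total 16S copies per mL of reactor sample: N = copies/µL × V_t / V_S."""
    if v_t <= 0 or v_s <= 0:
        raise ValueError("template and sample volumes must be positive")
    if copies_per_ul_template < 0:
        raise ValueError("copy concentration must be nonnegative")
    return copies_per_ul_template * v_t / v_s


def relative_abundance(counts: CountTable) -> tuple[pd.DataFrame, list[str]]:
    """Column-normalise counts to fractions.

    Returns the RA matrix restricted to samples with nonzero depth, plus the
    list of flagged zero-depth samples (excluded, never divided by zero).
    """
    depths = counts.depths()
    zero = [s for s in counts.samples if depths[s] == 0]
    if zero:
        log.warning("relative_abundance: zero-depth sample(s) excluded: %s", zero)
    keep = [s for s in counts.samples if depths[s] > 0]
    ra = counts.data[keep].astype(float) / depths[keep]
    return ra, zero


def estimated_absolute_abundance(n: pd.Series, ra: pd.DataFrame) -> AbundanceTable:
    """Scale relative abundance by the per-sample total copy number (EAA = N × RA)."""
    if set(n.index) != set(ra.columns):
        missing = set(ra.columns) ^ set(n.index)
        raise FormatError(f"sample mismatch between N and RA: {sorted(missing)}")
    n = n[ra.columns].astype(float)
    eaa = ra * n
    return AbundanceTable(eaa=eaa, ra=ra, n=n)


def rarefy(counts: CountTable, depth: int = 3000, seed: int | None = None) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; samples shallower than
    ``depth`` are dropped (logged).  Deterministic under a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    depths = counts.depths()
    kept, dropped = {}, []
    for sample in counts.samples:
        total = int(depths[sample])
        if total < depth:
            dropped.append(sample)
            continue
        col = counts.column(sample)
        kept[sample] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        log.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not kept:
        raise FormatError(f"all samples below rarefaction depth {depth}")
    out = pd.DataFrame(kept, index=counts.taxa)
    return CountTable(out)
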