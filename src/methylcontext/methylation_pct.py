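"""Percent methylation from paired methylated/unmethylated qPCR signal.

Dual-probe bisulfite qPCR (QAMA) and methylation-specific PCR both yield a
methylated and an unmethylated quantity per locus; percent methylation is
100 * M / (M + U). Quantities come from Ct values through per-channel
standard curves: a least-squares line of Ct on log10(quantity), inverted as
quantity = 10^((Ct - intercept)/slope). Curves with non-negative slope (no
amplification-efficiency signal) are flagged; quantification below the lowest
standard is extrapolated but flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # Ct per log10(quantity); negative for valid amplification
    intercept: float  # Ct at log10(quantity) = 0
    r_squared: float
    min_quantity: float  # lowest standard, floor for un-flagged quantification
    flagged: bool  # True when the fit is non-monotone (slope >= 0)

    def quantify(self, ct, warn_below_range: bool = True):
        """Inverse prediction of quantity from Ct; extrapolations below the
        lowest standard are allowed but flagged with a warning."""
        q = np.power(10.0, (np.asarray(ct, dtype=float) - self.intercept) / self.slope)
        if warn_below_range and np.any(q < self.min_quantity):
            warnings.warn(
                "quantity below the lowest standard; extrapolated", stacklevel=2
            )
        return q if np.ndim(ct) else float(q)


@dataclass(frozen=True)
class MethylationCall:
    locus: str
    methylated_quantity: float
    unmethylated_quantity: float

    @property
    def percent_methylated(self) -> float:
        return percent_methylated(self.methylated_quantity, self.unmethylated_quantity)


def fit_standard_curve(dilution_quantities, ct_values) -> StandardCurve:
    """Least-squares Ct ~ log10(quantity) from >= 3 standard points."""
    q = np.asarray(dilution_quantities, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if q.size != ct.size or q.size < 3:
        raise ValueError("need at least 3 matched dilution points")
    if np.any(q <= 0):
        raise ValueError("standard quantities must be positive")
    fit = stats.linregress(np.log10(q), ct)
    flagged = fit.slope >= 0
    if flagged:
        warnings.warn(
            "standard curve has non-negative slope; Ct not monotone in dilution",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        min_quantity=float(q.min()),
        flagged=bool(flagged),
    )


def percent_methylated(methylated, unmethylated):
    """100 * M / (M + U). Both zero is undefined and raises (never a silent 0)."""
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("quantities must be non-negative")
    total = m + u
    if np.any(total == 0):
        raise ValueError("percent methylation undefined when M + U = 0")
    out = 100.0 * m / total
    return out if out.ndim else float(out)


def compare_groups(percents_a, percents_b) -> tuple[float, float]:
    """Two-tailed t-test comparing percent-methylation between two groups."""
    t, p = stats.ttest_ind(np.asarray(percents_a), np.asarray(percents_b))
    return float(t), float(p)


def calls_from_quantities(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(locus, sample) percent methylation from a long quantity table with
    columns locus, sample, channel (methylated/unmethylated), quantity."""
    required = {"locus", "sample", "channel", "quantity"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(
        index=["locus", "sample"], columns="channel", values="quantity", aggfunc="sum"
    )
    for channel in ("methylated", "unmethylated"):
        if channel not in wide:
            raise ValueError(f"missing channel {channel!r}")
    out = wide.reset_index()
    out["percent_methylated"] = percent_methylated(
        out["methylated"].to_numpy(), out["unmethylated"].to_numpy()
    )
    return out[["locus", "sample", "methylated", "unmethylated", "percent_methylated"]]
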