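"""Viable-count arithmetic and CFU label-claim auditing.

Pour-plate triplicates are scaled by the dilution factor and averaged to a
final CFU/g; each product's measured count is compared with its label
claim on the log10 scale; the time-of-manufacture vs through-expiration
potency groups are compared with a two-sample t-test; and the DNA-yield
calibration converts a template concentration into a cell equivalent (the
limit-of-detection bookkeeping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import LabelClaim


@dataclass(frozen=True)
class PlateCount:
    colonies: tuple[int, int, int]
    dilution_factor: float
    cfu_per_g: float
    sd: float
    below_detection: bool = False


@dataclass(frozen=True)
class CfuComparison:
    product_id: str
    measured_cfu: float
    claimed_cfu: float
    log10_diff: float
    status: str                     # "above" or "below"
    excess_gt_1log: bool


@dataclass(frozen=True)
class YieldCalibration:
    """Cells in vs genomic-DNA concentration out for one standard extraction."""

    cells_in: float
    dna_conc_ng_per_ul: float

    def __post_init__(self) -> None:
        if self.cells_in <= 0 or self.dna_conc_ng_per_ul <= 0:
            raise ValueError("calibration values must be positive")


def cfu_from_plates(colonies: Sequence[int], dilution_factor: float) -> PlateCount:
    """Triplicate pour-plate arithmetic: mean(colonies) × dilution factor.

    The reported spread is the sample standard deviation of the three
    scaled counts.  All-zero plates flag the sample below detection.
    """
    if len(colonies) != 3:
        raise ValueError("expected triplicate colony counts")
    if any(c < 0 for c in colonies):
        raise ValueError("colony counts must be >= 0")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    scaled = np.asarray(colonies, dtype=float) * dilution_factor
    return PlateCount(
        colonies=tuple(int(c) for c in colonies),
        dilution_factor=float(dilution_factor),
        cfu_per_g=float(scaled.mean()),
        sd=float(scaled.std(ddof=1)),
        below_detection=all(c == 0 for c in colonies),
    )


def compare_claim(measured_cfu: float, claim: LabelClaim) -> CfuComparison:
    """Measured vs claimed CFU on the log10 scale.

    ``status`` is "above" when the measured count meets or exceeds the
    claim (a measurement exactly at claim counts as meeting it);
    ``excess_gt_1log`` marks overages beyond one order of magnitude.
    """
    if measured_cfu <= 0:
        raise ValueError("measured CFU must be positive")
    diff = math.log10(measured_cfu) - math.log10(claim.claimed_cfu_per_g)
    return CfuComparison(
        product_id=claim.product_id,
        measured_cfu=measured_cfu,
        claimed_cfu=claim.claimed_cfu_per_g,
        log10_diff=diff,
        status="above" if diff >= 0 else "below",
        excess_gt_1log=diff > 1.0,
    )


def summarize_claims(comparisons: Sequence[CfuComparison]) -> dict[str, float | int]:
    from .genotype import percentage
    n = len(comparisons)
    if n == 0:
        raise ValueError("no comparisons")
    above = sum(c.status == "above" for c in comparisons)
    return {
        "n_products": n,
        "n_above": above,
        "n_below": n - above,
        "n_excess_gt_1log": sum(c.excess_gt_1log for c in comparisons),
        "pct_above": percentage(above, n),
        "pct_below": percentage(n - above, n),
    }


def potency_basis_test(group_a: Sequence[float], group_b: Sequence[float],
                       log_scale: bool = True,
                       equal_var: bool = False) -> dict[str, float]:
    """Two-sample t-test between CFU groups (e.g. time-of-manufacture vs
    through-expiration labels).

    Defaults to Welch's test on log10 CFU; ``equal_var=True`` gives the
    pooled-variance variant and ``log_scale=False`` the raw-scale one.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("CFU must be positive for the log scale")
        a, b = np.log10(a), np.log10(b)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p)}


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def cells_per_concentration(target_conc_pg_per_ul: float,
                            cal: YieldCalibration,
                            sig_figures: int = 2) -> float:
    """Cell equivalent of a template concentration, via the yield calibration.

    cells = target / yield × cells_in, with the yield converted from ng/μL
    to pg/μL; reported to ``sig_figures`` significant figures as assay
    sensitivities conventionally are.
    """
    if target_conc_pg_per_ul <= 0:
        raise ValueError("target concentration must be positive")
    yield_pg_per_ul = cal.dna_conc_ng_per_ul * 1000.0
    cells = target_conc_pg_per_ul / yield_pg_per_ul * cal.cells_in
    return _round_sig(cells, sig_figures)


# ---------------------------------------------------------------------------
# Report export
# ---------------------------------------------------------------------------

def write_comparison_tsv(comparisons: Iterable[CfuComparison],
                         claims: dict[str, LabelClaim],
                         path: str | Path) -> None:
    rows = []
    for c in comparisons:
        claim = claims[c.product_id]
        rows.append({
            "product": c.product_id,
            "measured_cfu_per_g": f"{c.measured_cfu:.6g}",
            "claimed_cfu_per_g": f"{c.claimed_cfu:.6g}",
            "log10_diff": round(c.log10_diff, 3),
            "status": c.status,
            "months_to_expiration": claim.months_to_expiration,
            "potency_basis": claim.potency_basis,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plate_counts_tsv(path: str | Path) -> list[PlateCount]:
    df = pd.read_csv(path, sep="\t")
    needed = {"colony_1", "colony_2", "colony_3", "dilution_factor"}
    if not needed <= set(df.columns):
        raise ValueError(f"plate-count table needs columns {sorted(needed)}")
    return [cfu_from_plates((int(r.colony_1), int(r.colony_2), int(r.colony_3)),
                            float(r.dilution_factor))
            for r in df.itertuples()]
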