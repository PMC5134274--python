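"""De-regressed proofs (DRP) and effective daughter contributions (EDC).

A bull's published EBV blends progeny information with the parent average
(PA).  Using it directly as a pseudo-phenotype double-counts the parents, so
the parent-average contribution is removed and the remaining deviation is
re-expanded by the information it carries:

    alpha     = (4 - h2) / h2
    EDC(R)    = alpha * R / (1 - R)
    REL_PA    = (REL_sire + REL_dam) / 4
    EDC_prog  = EDC_EBV - EDC_PA
    DRP       = PA + (EBV - PA) * EDC_EBV / EDC_prog

Records whose derived progeny information is non-positive cannot be
de-regressed and are flagged and excluded (never clipped); the count is
logged.  Missing parent reliabilities are treated as zero.

``EDC_prog`` is carried through to the output as the natural weight of a
DRP; downstream REML is unweighted by default, with weights available as an
option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["BullRecord", "DRPRecord", "alpha_of", "edc_from_rel",
           "deregress_record", "deregress_table"]

INPUT_COLUMNS = ("id", "EBV", "PA", "REL_EBV", "REL_sire", "REL_dam")


@dataclass(frozen=True)
class BullRecord:
    EBV: float
    PA: float
    REL_EBV: float
    REL_sire: float
    REL_dam: float
    h2: float


@dataclass(frozen=True)
class DRPRecord:
    DRP: float
    EDC_EBV: float
    EDC_PA: float
    EDC_prog: float
    alpha: float
    REL_PA: float
    excluded: bool = False
    reason: str = ""


def alpha_of(h2: float) -> float:
    """``(4 - h2) / h2``; > 3 for any heritability below 1."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    return (4.0 - h2) / h2


def edc_from_rel(rel: float, alpha: float) -> float:
    """Effective daughter contribution implied by a reliability.

    ``alpha * rel / (1 - rel)``, monotone increasing in ``rel``.
    """
    if alpha <= 0.0:
        raise ValueError("alpha must be positive")
    if not 0.0 <= rel < 1.0:
        raise ValueError("reliability must be in [0, 1); rel = 1 implies infinite EDC")
    return alpha * rel / (1.0 - rel)


def deregress_record(rec: BullRecord) -> DRPRecord:
    """De-regress a single record (see module docstring for the chain)."""
    alpha = alpha_of(rec.h2)
    rel_sire = 0.0 if rec.REL_sire is None or np.isnan(rec.REL_sire) else rec.REL_sire
    rel_dam = 0.0 if rec.REL_dam is None or np.isnan(rec.REL_dam) else rec.REL_dam
    rel_pa = (rel_sire + rel_dam) / 4.0
    edc_ebv = edc_from_rel(rec.REL_EBV, alpha)
    edc_pa = edc_from_rel(rel_pa, alpha)
    edc_prog = edc_ebv - edc_pa
    if edc_prog <= 0.0:
        logger.warning(
            "record excluded: EDC_prog = %.4g <= 0 (EDC_EBV=%.4g, EDC_PA=%.4g)",
            edc_prog, edc_ebv, edc_pa,
        )
        return DRPRecord(DRP=np.nan, EDC_EBV=edc_ebv, EDC_PA=edc_pa,
                         EDC_prog=edc_prog, alpha=alpha, REL_PA=rel_pa,
                         excluded=True, reason="EDC_prog <= 0")
    drp = rec.PA + (rec.EBV - rec.PA) * edc_ebv / edc_prog
    return DRPRecord(DRP=drp, EDC_EBV=edc_ebv, EDC_PA=edc_pa, EDC_prog=edc_prog,
                     alpha=alpha, REL_PA=rel_pa)


def deregress_table(records: pd.DataFrame, h2: float | None = None) -> pd.DataFrame:
    """Vectorized de-regression of a bull-record table.

    ``records`` needs columns ``id, EBV, PA, REL_EBV, REL_sire, REL_dam`` and
    either an ``h2`` column or the ``h2`` argument.  Returns the input plus
    ``DRP, EDC_EBV, EDC_PA, EDC_prog, excluded_flag`` columns; excluded rows
    keep NaN DRP and are counted in the log.
    """
    missing = set(INPUT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"bull-record table lacks columns {sorted(missing)}")
    if h2 is None:
        if "h2" not in records.columns:
            raise ValueError("supply h2 as an argument or a column")
        h2_vec = records["h2"].to_numpy(dtype=float)
    else:
        h2_vec = np.full(len(records), float(h2))
    alpha = (4.0 - h2_vec) / h2_vec
    rel_ebv = records["REL_EBV"].to_numpy(dtype=float)
    if np.any(rel_ebv >= 1.0) or np.any(rel_ebv < 0.0):
        raise ValueError("REL_EBV must be in [0, 1)")
    rel_pa = (np.nan_to_num(records["REL_sire"].to_numpy(dtype=float))
              + np.nan_to_num(records["REL_dam"].to_numpy(dtype=float))) / 4.0
    edc_ebv = alpha * rel_ebv / (1.0 - rel_ebv)
    edc_pa = alpha * rel_pa / (1.0 - rel_pa)
    edc_prog = edc_ebv - edc_pa
    excluded = edc_prog <= 0.0
    ebv = records["EBV"].to_numpy(dtype=float)
    pa = records["PA"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        drp = np.where(excluded, np.nan, pa + (ebv - pa) * edc_ebv / edc_prog)
    if excluded.any():
        logger.warning("%d of %d records excluded (EDC_prog <= 0)",
                       int(excluded.sum()), len(records))
    out = records.copy()
    out["DRP"] = drp
    out["EDC_EBV"] = edc_ebv
    out["EDC_PA"] = edc_pa
    out["EDC_prog"] = edc_prog
    out["excluded_flag"] = excluded
    return out
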