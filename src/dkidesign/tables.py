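"""Protocol-table generation and CSV round-tripping.

A protocol table has one row per (n, K) cell and mirrors the layout of
the published optimal-design tables: the design (as bD values), the model
bound (bD)_max = 3/K, the target kurtosis, and the three coefficients of
variation at the reference SNR.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crlb import evaluate_protocol
from .model import DIMENSIONLESS_BD, Protocol, TissueParams
from .optimizer import (
    OptimizationSpec,
    equally_spaced_protocol,
    max_allowable_bd,
    optimize_protocol,
)

__all__ = [
    "TABLE_COLUMNS",
    "DEFAULT_CELLS",
    "ProtocolTableError",
    "optimized_design_table",
    "equally_spaced_table",
    "write_protocol_table",
    "read_protocol_table",
]

TABLE_COLUMNS = ["n", "design_bd", "bd_max", "k", "cov_k", "cov_d", "cov_s0"]

#: The 18 (n, K) cells of the reference tables: 3-5 acquisitions crossed
#: with kurtosis targets spanning head-and-neck to low-kurtosis tissue.
DEFAULT_CELLS: tuple[tuple[int, float], ...] = tuple(
    (n, k) for n in (3, 4, 5) for k in (1.5, 1.0, 0.8, 0.6, 0.5, 0.3)
)


class ProtocolTableError(ValueError):
    """A protocol-table file failed to parse."""


def _format_design(bvalues: Iterable[float]) -> str:
    return ";".join(f"{b:.6g}" for b in bvalues)


def _parse_design(text: str) -> tuple[float, ...]:
    return tuple(float(tok) for tok in str(text).split(";"))


def _row(n: int, design, bd_max: float, k: float, covs) -> dict:
    return {
        "n": n,
        "design_bd": _format_design(design),
        "bd_max": round(bd_max, 10),
        "k": k,
        "cov_k": covs.cov_k,
        "cov_d": covs.cov_d,
        "cov_s0": covs.cov_s0,
    }


def optimized_design_table(
    cells: Sequence[tuple[int, float]] = DEFAULT_CELLS,
    snr: float = 20.0,
    grid_step: float = 0.05,
    s0: float = 1.0,
    d: float = 1.0,
    objective: str = "cov_d_plus_cov_k",
    search_mode: str = "auto",
) -> pd.DataFrame:
    """Optimal design and CoVs for each (n, K) cell."""
    rows = []
    for n, k in cells:
        params = TissueParams(s0=s0, d=d, k=k)
        spec = OptimizationSpec(
            n=n, grid_step=grid_step, objective=objective, search_mode=search_mode
        )
        res = optimize_protocol(spec, params, snr=snr)
        rows.append(
            _row(n, res.best_protocol.bvalues, max_allowable_bd(k), k, res.covs)
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def equally_spaced_table(
    cells: Sequence[tuple[int, float]] = DEFAULT_CELLS,
    snr: float = 20.0,
    s0: float = 1.0,
    d: float = 1.0,
) -> pd.DataFrame:
    """Equally spaced reference designs (0 to (bD)_max) and their CoVs."""
    rows = []
    for n, k in cells:
        params = TissueParams(s0=s0, d=d, k=k)
        bd_max = max_allowable_bd(k)
        protocol = equally_spaced_protocol(n, bd_max, snr=snr)
        covs = evaluate_protocol(protocol, params)
        rows.append(_row(n, protocol.bvalues, bd_max, k, covs))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_protocol_table(table: pd.DataFrame, path) -> None:
    """Write a protocol table as RFC-4180 CSV (C locale, '.' decimal)."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ProtocolTableError(f"table is missing columns {missing}")
    out = table[TABLE_COLUMNS].copy()
    for col in ("bd_max", "k", "cov_k", "cov_d", "cov_s0"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, index=False)


def read_protocol_table(path) -> pd.DataFrame:
    """Read a protocol table written by :func:`write_protocol_table`.

    Raises
    ------
    ProtocolTableError
        On missing columns or unparseable fields, with the offending
        line number where available.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as err:  # pandas raises several parse error types
        raise ProtocolTableError(f"{path}: {err}") from None
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ProtocolTableError(f"{path}: missing columns {missing}")
    for i, text in enumerate(table["design_bd"]):
        try:
            _parse_design(text)
        except ValueError:
            raise ProtocolTableError(
                f"{path}: line {i + 2}: bad design field {text!r}"
            ) from None
    for col in ("n",):
        table[col] = table[col].astype(int)
    for col in ("bd_max", "k", "cov_k", "cov_d", "cov_s0"):
        try:
            table[col] = table[col].astype(float)
        except ValueError as err:
            raise ProtocolTableError(f"{path}: column {col}: {err}") from None
    return table[TABLE_COLUMNS]


def designs_from_table(table: pd.DataFrame) -> list[tuple[float, ...]]:
    """The designs of a table as tuples of bD values."""
    return [_parse_design(t) for t in table["design_bd"]]
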