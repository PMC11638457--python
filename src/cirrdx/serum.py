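"""Serum fibrosis indices FIB-4 and APRI.

FIB-4 = (age [y] x AST [U/L]) / (platelet [10^9/L] x sqrt(ALT [U/L]))
APRI  = (AST / AST-ULN) / platelet [10^9/L] x 100
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["SerumConfig", "fib4", "apri", "add_serum_indices"]


@dataclass(frozen=True)
class SerumConfig:
    ast_uln: float = 40.0  # U/L; study value unreported, configurable

    def __post_init__(self):
        if self.ast_uln <= 0:
            raise ConfigurationError("ast_uln must be positive")


def fib4(age, ast, platelet, alt):
    """Vectorized; raises on nonpositive platelet or ALT."""
    age, ast, platelet, alt = (np.asarray(v, dtype=float) for v in (age, ast, platelet, alt))
    if np.any(platelet <= 0):
        raise DomainError("platelet count must be positive")
    if np.any(alt <= 0):
        raise DomainError("ALT must be positive")
    out = (age * ast) / (platelet * np.sqrt(alt))
    return float(out) if out.ndim == 0 else out


def apri(ast, platelet, cfg: SerumConfig = SerumConfig()):
    ast, platelet = np.asarray(ast, dtype=float), np.asarray(platelet, dtype=float)
    if np.any(platelet <= 0):
        raise DomainError("platelet count must be positive")
    out = (ast / cfg.ast_uln) / platelet * 100.0
    return float(out) if out.ndim == 0 else out


def add_serum_indices(df: pd.DataFrame, cfg: SerumConfig = SerumConfig()) -> pd.DataFrame:
    """Return a copy of the cohort table with ``fib4`` and ``apri`` columns."""
    out = df.copy()
    out["fib4"] = fib4(df["age"], df["ast"], df["platelet"], df["alt"])
    out["apri"] = apri(df["ast"], df["platelet"], cfg)
    return out
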