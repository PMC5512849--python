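"""Parameter sets: loading, validation and round-trip serialization.

Parameters are flat symbol -> value tables with units and provenance, accepted
either as tidy CSV (columns: symbol, value, units, provenance) or as YAML
mapping.  The packaged default (``data/ecoli_params.csv``) is a curated set,
every entry flagged ``provenance: refit``, calibrated so the model reproduces
the qualitative and headline quantitative fermentation behavior of the
wild-type strain and the fnr/arcA/pfl knockouts across dissolved-oxygen
levels.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = ["ParameterSet", "ParameterValidationError", "load_parameters"]

#: symbols every parameter set must provide beyond what the network references
GLOBAL_SYMBOLS = (
    "K_Fnr",
    "K_ArcA",
    "n_hill",
    "k_O2",
    "DO2_star",
    "k_ATP",
    "X_carbon",
    "drain_K",
)

#: symbols that must be strictly positive
_POSITIVE_PREFIXES = ("K_", "vmax_", "Keq_", "beta_", "a_", "r_")
_POSITIVE_GLOBALS = {"K_Fnr", "K_ArcA", "DO2_star", "k_ATP", "X_carbon", "drain_K"}
# beta_/a_/r_ (regulation and activation strengths) must be >= 0, K_ > 0


class ParameterValidationError(ValueError):
    """Raised with the exhaustive list of offending symbols."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid parameter set (%d problem%s):\n  %s"
            % (len(problems), "s" if len(problems) != 1 else "", "\n  ".join(problems))
        )


@dataclass
class ParameterSet:
    """Validated flat parameter table with provenance metadata."""

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    #: transcription-factor activity scales; set to 0.0 by gene knockouts
    tf_scale: dict[str, float] = field(default_factory=lambda: {"Fnr": 1.0, "ArcA": 1.0})

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.values

    def get(self, symbol: str, default: float | None = None):
        return self.values.get(symbol, default)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            values=dict(self.values),
            units=dict(self.units),
            provenance=dict(self.provenance),
            tf_scale=dict(self.tf_scale),
        )

    def with_values(self, **overrides: float) -> "ParameterSet":
        new = self.copy()
        new.values.update(overrides)
        return new

    # -- serialization ----------------------------------------------------
    def to_csv(self, path_or_buf=None) -> str | None:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["symbol", "value", "units", "provenance"])
        for sym in sorted(self.values):
            writer.writerow(
                [
                    sym,
                    repr(self.values[sym]),  # repr round-trips floats exactly
                    self.units.get(sym, ""),
                    self.provenance.get(sym, ""),
                ]
            )
        text = buf.getvalue()
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        return None

    def digest(self) -> str:
        """Stable hex digest of the numeric content (used by golden regressions)."""
        import hashlib

        h = hashlib.sha256()
        for sym in sorted(self.values):
            h.update(f"{sym}={self.values[sym]!r};".encode())
        for tf in sorted(self.tf_scale):
            h.update(f"tf:{tf}={self.tf_scale[tf]!r};".encode())
        return h.hexdigest()[:16]


def _validate(params: ParameterSet, required: Iterable[str]) -> None:
    problems = []
    for sym in sorted(set(required) | set(GLOBAL_SYMBOLS)):
        if not sym:
            continue
        if sym not in params.values:
            problems.append(f"missing parameter: {sym}")
    for sym, val in params.values.items():
        if not math.isfinite(val):
            problems.append(f"non-finite value for {sym}: {val}")
            continue
        if sym in _POSITIVE_GLOBALS or sym.startswith(("K_", "vmax_")) and sym != "vmax_":
            # vmax may legitimately be zero (knockout), K must be > 0
            if sym.startswith("K_") or sym in _POSITIVE_GLOBALS:
                if val <= 0:
                    problems.append(f"non-positive value for {sym}: {val}")
        if sym.startswith(("a_", "r_", "beta_")) and val < 0:
            problems.append(f"negative regulation strength {sym}: {val}")
        if sym.startswith("vmax_") and val < 0:
            problems.append(f"negative vmax {sym}: {val}")
    if "n_hill" in params.values and params.values["n_hill"] >= 0:
        problems.append(f"Hill coefficient n_hill must be negative, got {params.values['n_hill']}")
    if "k_O2" in params.values and not (0 < params.values["k_O2"] <= 1):
        problems.append(
            f"k_O2 must lie in (0, 1] (cytoplasmic O2 below medium DO), got {params.values['k_O2']}"
        )
    if problems:
        raise ParameterValidationError(problems)


def load_parameters(source=None, required_symbols: Iterable[str] = ()) -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` may be a CSV/YAML path, an open stream (CSV if first line looks
    like the tidy header, YAML otherwise), a mapping, or None for the packaged
    default.  Missing/invalid symbols are reported exhaustively in a single
    :class:`ParameterValidationError`.
    """
    if source is None:
        ref = resources.files("aeroferm.data").joinpath("ecoli_params.csv")
        with ref.open("r") as fh:
            return load_parameters(fh, required_symbols)
    if isinstance(source, Mapping):
        params = ParameterSet(values={k: float(v) for k, v in source.items()})
        _validate(params, required_symbols)
        return params
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    text = text.lstrip("﻿")
    first = text.splitlines()[0] if text.splitlines() else ""
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    provenance: dict[str, str] = {}
    if first.replace(" ", "").lower().startswith("symbol,value"):
        reader = csv.DictReader(io.StringIO(text))
        for row in reader:
            sym = row["symbol"].strip()
            values[sym] = float(row["value"])
            units[sym] = (row.get("units") or "").strip()
            provenance[sym] = (row.get("provenance") or "").strip()
    else:
        doc = yaml.safe_load(text)
        if not isinstance(doc, Mapping):
            raise ParameterValidationError(["unrecognized parameter file format"])
        for sym, val in doc.items():
            values[str(sym)] = float(val)
    params = ParameterSet(values=values, units=units, provenance=provenance)
    _validate(params, required_symbols)
    return params
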