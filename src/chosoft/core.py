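"""Shared domain types and tidy-table plumbing.

Every stage of the package speaks one language: a tidy long-format table of
culture observations with columns ``batch_id, condition, replicate, time_h,
channel, value``.  Channels are sampled on different cadences in fed-batch
experiments, so the long format represents "not measured" naturally as an
absent or empty cell; missing values are first-class (NaN), never coded as
0 or -1.  Time is always in hours.
"""

from __future__ import annotations

import enum
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("chosoft")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s chosoft: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: reserved replicate id marking a replicate-pooled pseudo-flask
POOLED_REPLICATE = 0

CSV_COLUMNS = ["batch_id", "condition", "replicate", "time_h", "channel", "value"]


class ChannelRole(enum.Enum):
    FACTOR = "factor"
    RESPONSE = "response"
    BOTH = "both"


class Channel(enum.Enum):
    """Measured quantity identifiers, with units and model role.

    The member name itself is part of the value tuple so that channels
    sharing units and role stay distinct enum members.
    """

    VCD = ("VCD", "cells/mL", ChannelRole.RESPONSE)
    TITER = ("TITER", "mg/L", ChannelRole.RESPONSE)
    GLC = ("GLC", "mM", ChannelRole.FACTOR)
    GLN = ("GLN", "mM", ChannelRole.FACTOR)
    GLU = ("GLU", "mM", ChannelRole.FACTOR)
    LAC = ("LAC", "mM", ChannelRole.FACTOR)
    NH4 = ("NH4", "mM", ChannelRole.FACTOR)
    GAL = ("GAL", "mM", ChannelRole.FACTOR)
    UDP_GLC = ("UDP_GLC", "mM", ChannelRole.RESPONSE)
    UDP_GAL = ("UDP_GAL", "mM", ChannelRole.RESPONSE)
    UDP_GLCNAC = ("UDP_GLCNAC", "mM", ChannelRole.RESPONSE)
    UDP_GALNAC = ("UDP_GALNAC", "mM", ChannelRole.RESPONSE)
    G0F = ("G0F", "%", ChannelRole.RESPONSE)
    G1F = ("G1F", "%", ChannelRole.RESPONSE)
    G2F = ("G2F", "%", ChannelRole.RESPONSE)

    def __init__(self, _key: str, units: str, role: ChannelRole):
        self.units = units
        self.role = role

    @property
    def is_glycan(self) -> bool:
        return self in (Channel.G0F, Channel.G1F, Channel.G2F)

    @property
    def is_nsd(self) -> bool:
        return self in (Channel.UDP_GLC, Channel.UDP_GAL,
                        Channel.UDP_GLCNAC, Channel.UDP_GALNAC)


#: factor set for the data-driven soft sensors (extracellular metabolites)
FACTOR_CHANNELS = [Channel.GLC, Channel.GLN, Channel.NH4,
                   Channel.LAC, Channel.GLU, Channel.GAL]
#: response set for the data-driven soft sensors
RESPONSE_CHANNELS = [Channel.G0F, Channel.G1F, Channel.G2F,
                     Channel.UDP_GAL, Channel.UDP_GLC,
                     Channel.UDP_GALNAC, Channel.UDP_GLCNAC,
                     Channel.VCD, Channel.TITER]

CONDITIONS = ("Control", "A", "B", "Validation")


class SchemaError(ValueError):
    """Input file does not have the required structure."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


@dataclass
class CultureTable:
    """Tidy long-format culture observations.

    Wraps a DataFrame with columns ``batch_id, condition, replicate, time_h,
    channel, value``.  ``channel`` holds :class:`Channel` names (strings in
    the frame); ``value`` is float with NaN for missing.  Measured
    concentrations/counts are non-negative and glycan fractions lie in
    [0, 100]; model *predictions* may violate this, so construct prediction
    tables with ``validate=False``.
    """

    df: pd.DataFrame
    validate: bool = True

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df[CSV_COLUMNS].reset_index(drop=True)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        df["time_h"] = df["time_h"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        unknown = set(df["channel"]) - {c.name for c in Channel}
        if unknown:
            raise SchemaError(f"unknown channels: {sorted(unknown)}")
        if self.validate:
            neg = df["value"].notna() & (df["value"] < 0)
            if neg.any():
                row = df.index[neg][0]
                raise ValidationError(
                    f"negative value in row {row}: "
                    f"{df.loc[row, 'channel']} = {df.loc[row, 'value']}"
                )
            gly = df["channel"].isin(["G0F", "G1F", "G2F"])
            bad = gly & df["value"].notna() & (df["value"] > 100)
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(f"glycan fraction > 100 in row {row}")
            key = df[["batch_id", "replicate", "time_h", "channel"]]
            if key.duplicated().any():
                dup = df[key.duplicated()].iloc[0]
                raise ValidationError(
                    f"duplicate observation: {tuple(dup[:5])}"
                )
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, *, condition: str | None = None,
               channels: Iterable[Channel] | None = None) -> "CultureTable":
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
        if channels is not None:
            names = {c.name for c in channels}
            df = df[df["channel"].isin(names)]
        return CultureTable(df.reset_index(drop=True), validate=False)

    def wide(self) -> pd.DataFrame:
        """Wide view: one row per (batch_id, condition, replicate, time_h)."""
        return self.df.pivot_table(
            index=["batch_id", "condition", "replicate", "time_h"],
            columns="channel", values="value", aggfunc="first",
            dropna=False,
        ).reset_index()

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, na_rep="")


def read_culture_table(path: str | Path,
                       schema: Sequence[Channel] | None = None,
                       validate: bool = True) -> CultureTable:
    """Read a tidy culture CSV.

    Unparseable numeric cells become missing (with a warning); channels
    outside ``schema`` (default: all known channels) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    raw = df["value"].replace("", np.nan)
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & parsed.isna()
    if bad.any():
        logger.warning("%s: %d unparseable numeric cells set to missing",
                       path, int(bad.sum()))
    df["value"] = parsed
    if schema is not None:
        allowed = {c.name for c in schema}
        unknown = set(df["channel"]) - allowed
        if unknown:
            raise SchemaError(f"{path}: channels outside schema: {sorted(unknown)}")
    return CultureTable(df, validate=validate)


def normalize_glycan_fractions(areas: Sequence[float]) -> np.ndarray:
    """Normalize three glycan peak areas (G0F, G1F, G2F AUC) to percent.

    Fractions are 100 * area / sum(areas); the output sums to exactly 100
    up to rounding and is invariant to positive rescaling of the input.
    """
    a = np.asarray(areas, dtype=float)
    if a.shape != (3,):
        raise ValueError("expected exactly three peak areas (G0F, G1F, G2F)")
    if (a < 0).any():
        raise ValidationError("peak areas must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValidationError("all peak areas zero: glycan composition undefined")
    return 100.0 * a / total


def pool_replicates(table: CultureTable, condition: str) -> CultureTable:
    """Average biological replicates of one condition into a pooled pseudo-flask.

    Per (time, channel) the mean is taken over replicates with non-missing
    values; the result is missing only when every replicate is missing.  The
    pooled rows carry ``replicate = POOLED_REPLICATE``.
    """
    sub = table.df[table.df["condition"] == condition]
    if sub.empty:
        return CultureTable(sub.copy(), validate=False)
    pooled = (
        sub.groupby(["time_h", "channel"], as_index=False)["value"]
        .mean()  # skipna by default; all-NaN group -> NaN
    )
    pooled["batch_id"] = f"{condition}-pooled"
    pooled["condition"] = condition
    pooled["replicate"] = POOLED_REPLICATE
    return CultureTable(pooled[CSV_COLUMNS], validate=False)


def load_config(path: str | Path) -> dict:
    """Load the YAML config (keys: design, kinetics, noise, missingness,
    opls, nn, stats, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config root must be a mapping")
    return cfg
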