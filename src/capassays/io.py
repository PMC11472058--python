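"""Shared table readers/writers and run configuration.

Three delimited-text dialects are supported: ``generic_csv``,
``generic_tsv`` and ``maxquant_proteingroups``.  The MaxQuant dialect maps
the proteinGroups.txt columns ("Reporter intensity corrected N",
"Razor + unique peptides", "Reverse", "Only identified by site",
"Potential contaminant", "iBAQ") onto the pipeline's internal names; the
QC flag columns use MaxQuant's "+" marker convention.  A configurable
``column_map`` covers other dialects.

Ground-truth sidecars for synthetic data are flat ``key = value`` text files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .proteomics import channel_columns

log = logging.getLogger("capassays")

__all__ = [
    "read_table",
    "write_table",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "RunConfig",
]

DIALECTS = ("generic_csv", "generic_tsv", "maxquant_proteingroups")

#: MaxQuant proteinGroups.txt -> internal column names
MAXQUANT_MAP = {
    **{f"Reporter intensity corrected {i}": f"reporter_{i}" for i in range(1, 10)},
    "Razor + unique peptides": "razor_unique_peptides",
    "iBAQ": "ibaq",
    "Protein IDs": "group_id",
}
MAXQUANT_FLAGS = {
    "Reverse": "flag_reverse",
    "Only identified by site": "flag_site_only",
    "Potential contaminant": "flag_contaminant",
}


def read_table(path, dialect: str = "generic_csv",
               column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a delimited table in one of the known dialects."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if dialect == "generic_csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"empty input file: {path}") from e
    if df.empty and df.columns.empty:
        raise ValueError(f"empty input file: {path}")
    if dialect == "maxquant_proteingroups":
        df = _map_maxquant(df, column_map)
    elif column_map:
        df = df.rename(columns=column_map)
    log.info("read %s: %d rows x %d columns", path, len(df), df.shape[1])
    return df


def _map_maxquant(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    mapping = dict(MAXQUANT_MAP)
    flags = dict(MAXQUANT_FLAGS)
    if column_map:
        mapping.update(column_map)
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise ValueError(f"proteinGroups table missing mandatory columns: {missing}")
    out = df.rename(columns=mapping)
    for src, dst in flags.items():
        if src not in df.columns:
            raise ValueError(f"proteinGroups table missing flag column {src!r}")
        out[dst] = df[src].astype(str).str.strip().eq("+")
        if src != dst:
            out = out.drop(columns=[src])
    for c in channel_columns() + ["ibaq"]:
        bad = pd.to_numeric(out[c], errors="coerce").isna() & out[c].notna()
        if bad.any():
            raise ValueError(
                f"malformed numerics in column {c!r} at rows {list(out.index[bad][:5])}")
        out[c] = pd.to_numeric(out[c], errors="coerce")
    return out


def write_table(df: pd.DataFrame, path, dialect: str = "generic_csv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if dialect == "generic_csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def write_truth_sidecar(truth: dict, path) -> None:
    """Write ground truth as flat ``key = value`` lines (JSON-encoded values)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in truth.items():
            if isinstance(val, np.ndarray):
                val = val.tolist()
            fh.write(f"{key} = {json.dumps(val)}\n")


def read_truth_sidecar(path) -> dict:
    truth = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        truth[key.strip()] = json.loads(val.strip())
    return truth


_KNOWN_STAGES = ("binding", "quantitation", "densitometry", "expression",
                 "proteomics")
_KNOWN_TOP = ("seed", "outdir") + _KNOWN_STAGES


class RunConfig:
    """Validated pipeline configuration (YAML).

    Top-level keys: ``seed`` (int, fans out to per-stage seeds), ``outdir``
    and one block per stage to run.  Unknown keys are rejected so typos fail
    loudly rather than silently skipping a stage.
    """

    def __init__(self, data: dict):
        unknown = set(data) - set(_KNOWN_TOP)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(data.get("seed", 0))
        self.outdir = Path(data.get("outdir", "results/run"))
        self.stages = {k: data[k] for k in _KNOWN_STAGES if k in data}
        if not self.stages:
            raise ValueError("config enables no stages")
        self._data = data

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed (< 2^31)."""
        idx = _KNOWN_STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1)[0] % (2**31))

    def digest(self) -> str:
        import hashlib
        blob = json.dumps(self._data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
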