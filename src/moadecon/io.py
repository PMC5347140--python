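"""Validated CSV readers/writers and the run configuration.

All concentration columns are molar on disk; display units (uM) appear only
in reports.  Readers validate against a lightweight schema and report
failing rows with their CSV line numbers (header = line 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["Schema", "SCHEMAS", "read_tidy_csv", "RunConfig"]


@dataclass(frozen=True)
class Schema:
    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    positive: tuple[str, ...] = ()  # numeric and strictly > 0


SCHEMAS = {
    "dose_response": Schema(
        "dose_response",
        required=("drug", "cell_line", "readout", "conc_M", "response"),
        numeric=("conc_M", "response"),
        positive=("conc_M",),
    ),
    "nuclei": Schema(
        "nuclei",
        required=("well_id", "dna_int", "phh3_mean", "phh3_max", "border"),
        numeric=("dna_int", "phh3_mean", "phh3_max"),
    ),
    "kymo_events": Schema(
        "kymo_events",
        required=("id", "phase", "length_um", "duration_s", "end_fate", "complete"),
        numeric=("length_um", "duration_s"),
        positive=("duration_s",),
    ),
    "turbidity": Schema(
        "turbidity",
        required=("well", "condition", "conc_M", "time_min", "od340"),
        numeric=("time_min", "od340"),
    ),
    "binding_plate": Schema(
        "binding_plate",
        required=("well", "conc_M", "s665", "s620", "role"),
        numeric=("s665", "s620"),
    ),
    "auc": Schema(
        "auc",
        required=("dose_mg", "auc_um_h"),
        numeric=("dose_mg", "auc_um_h"),
        positive=("auc_um_h",),
    ),
}


def read_tidy_csv(path: str | Path, schema: str | Schema,
                  strict: bool = True) -> pd.DataFrame:
    """Read and validate a tidy CSV against a named schema.

    Missing columns raise immediately.  Rows with non-numeric or
    non-positive values in constrained columns are rejected: with
    ``strict=True`` a ValueError lists the offending CSV line numbers; with
    ``strict=False`` the rows are dropped with a warning.
    """
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    df = pd.read_csv(path)
    missing = [c for c in sch.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}
    for col in sch.numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        nn = vals.isna() & df[col].notna()
        for i in df.index[nn]:
            reasons.setdefault(i, f"non-numeric {col}")
        bad |= nn
        df[col] = vals
    for col in sch.positive:
        np_bad = df[col].notna() & ~(df[col] > 0)
        for i in df.index[np_bad]:
            reasons.setdefault(i, f"non-positive {col}")
        bad |= np_bad

    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        lines = [f"line {i + 2}: {reasons[i]}" for i in df.index[bad]]
        msg = f"{path}: {int(bad.sum())} invalid row(s): " + "; ".join(lines[:20])
        if strict:
            raise ValueError(msg)
        logger.warning("%s (rows dropped)", msg)
        df = df[~bad]
    return df.reset_index(drop=True)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the package defaults.

    Thresholds: the PI3K engagement regarded as required for a cytostatic
    proliferation block (percent pPKB inhibition) and the tolerated fraction
    of maximal mitotic (pHH3) response; the 20 uM non-responder cap; the
    ambiguity rule's relative slope-error bound; mode-anchored cell-cycle
    gate ratios.
    """

    seed: int = 0
    n_lines: int = 44
    n_replicates: int = 2
    scenario: str = "full"  # which drug set to simulate
    outdir: str = "results"
    pi3k_required_pct: float = 90.0
    mda_tolerated_pct: float = 20.0
    nonresponder_cap_m: float = 20e-6
    phh3_min_response_pct: float = 5.0
    phh3_threshold_percentile: float = 99.0
    cycle_gates: dict = field(default_factory=lambda: {
        "subg1": 0.6, "g1_hi": 1.3, "s_hi": 1.7, "g2m_hi": 2.6})
    run_optional_stages: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def dose_response_frame(panels: dict) -> pd.DataFrame:
    """Flatten ``gen_study``/``gen_panel`` output into a tidy CSV frame."""
    rows = []
    for drug, lines in panels.items():
        for line, readouts in lines.items():
            for rdt, ds in readouts.items():
                for c, r, rep in zip(ds.conc_m, ds.response,
                                     ds.replicate if ds.replicate is not None
                                     else np.zeros(ds.conc_m.size, int)):
                    rows.append({"drug": drug, "cell_line": line, "readout": rdt,
                                 "conc_M": c, "response": r, "replicate": int(rep)})
    return pd.DataFrame(rows)
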