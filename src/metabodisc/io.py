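"""Readers and writers for the CSV/TSV table formats and JSON result bundles."""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import FeatureTable, PipelineConfig, Role, SampleMeta

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}


def read_feature_table(path: str | Path, delimiter: str | None = None) -> FeatureTable:
    """Read a feature table: first column sample ids, header metabolite ids.

    Blank cells and "NA"-style tokens denote missing values and are flagged in
    the missing mask.  Malformed numeric cells and duplicate ids raise, never
    silently coerce.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    metabolite_ids = [str(c) for c in df.columns]
    for ids, what in [(sample_ids, "sample"), (metabolite_ids, "metabolite")]:
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate {what} id: {dupes.iloc[0]!r}")
    values = np.zeros(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell.lower() in _MISSING_TOKENS:
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at sample {sample_ids[i]!r}, "
                        f"metabolite {metabolite_ids[j]!r}"
                    ) from None
    return FeatureTable(sample_ids, metabolite_ids, values, mask)


def write_feature_table(table: FeatureTable, path: str | Path, delimiter: str = ",") -> None:
    df = table.to_dataframe()
    df.to_csv(Path(path), sep=delimiter, index_label="sample_id", na_rep="NA")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata CSV with columns sample_id, role, outcome[, run_order]."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    records: list[SampleMeta] = []
    for _, row in df.iterrows():
        role_str = row["role"].strip().lower()
        try:
            role = Role(role_str)
        except ValueError:
            raise ValueError(f"unknown role {row['role']!r} for sample {row['sample_id']!r}") from None
        outcome_cell = str(row.get("outcome", "")).strip()
        if role is Role.QC:
            if outcome_cell not in _MISSING_TOKENS:
                raise ValueError(f"QC sample {row['sample_id']!r} must not carry an outcome")
            y = None
        else:
            if outcome_cell in _MISSING_TOKENS:
                raise ValueError(f"{role.value} sample {row['sample_id']!r} lacks an outcome")
            y = int(outcome_cell)
        run_cell = str(row.get("run_order", "")).strip()
        run_order = int(run_cell) if run_cell not in _MISSING_TOKENS else None
        records.append(SampleMeta(str(row["sample_id"]), role, y, run_order))
    return records


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "role": m.role.value,
            "outcome": "" if m.y is None else m.y,
            "run_order": "" if m.run_order is None else m.run_order,
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# -- result bundle ------------------------------------------------------


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


@dataclass
class ResultBundle:
    """Per-stage outputs with parameters and seed provenance.

    Serialization round-trips: write followed by read yields identical
    numerical content (JSON full float precision).
    """

    stages: dict[str, dict] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def record(self, stage: str, parameters: dict, outputs: dict) -> None:
        self.stages[stage] = {"parameters": _jsonify(parameters), "outputs": _jsonify(outputs)}

    def write(self, path: str | Path) -> None:
        payload = {"stages": self.stages, "provenance": _jsonify(self.provenance)}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "ResultBundle":
        payload = json.loads(Path(path).read_text())
        return cls(stages=payload["stages"], provenance=payload["provenance"])


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def read_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; omitted sections take the defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
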