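"""Tab-separated I/O with machine-readable provenance headers.

All tables are UTF-8 TSV with a header row and '.' decimals.  Lines opening
with '#' before the header carry provenance (``# key=value``), at minimum
the seed and a hash of the run configuration; readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "config_hash",
    "write_tsv",
    "read_tsv",
    "write_region_counts",
    "read_region_counts",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(path, df: pd.DataFrame, provenance: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_region_counts(path, counts: pd.DataFrame, design: pd.DataFrame,
                        provenance: dict | None = None) -> None:
    """Write an animals x regions matrix joined with its pair design."""
    merged = design.set_index("animal_id").join(counts)
    write_tsv(path, merged.reset_index(), provenance=provenance)


def read_region_counts(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a region-count TSV; returns (counts indexed by animal, design frame)."""
    df = read_tsv(path)
    needed = {"animal_id", "pair_id", "group"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"region-count table {path} lacks columns {sorted(missing)}")
    design = df[["animal_id", "pair_id", "group"]].copy()
    counts = df.drop(columns=["pair_id", "group"]).set_index("animal_id")
    bad = [c for c in counts.columns if not pd.api.types.is_numeric_dtype(counts[c])]
    if bad:
        raise ValueError(f"non-numeric region columns in {path}: {bad}")
    return counts, design
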