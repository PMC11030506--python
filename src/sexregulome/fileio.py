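"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic intervals use BED semantics: 0-based, half-open. Tables are
UTF-8, tab-delimited, with a header row. Contact maps are 3-column bin-pair
tables with the resolution carried separately; ``bin = floor(pos / resolution)``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

BED_COLUMNS = ["chrom", "start", "end", "name"]


def chrom_class(name: str) -> str:
    """Classify a chromosome name as ``autosome``, ``X`` or ``Y``.

    Mitochondrial contigs are rejected: mitochondrial reads are removed
    upstream of any accessibility analysis and their presence indicates a
    mis-specified input.
    """
    base = name[3:] if name.lower().startswith("chr") else name
    if base.upper() == "X":
        return "X"
    if base.upper() == "Y":
        return "Y"
    if base.upper() in {"M", "MT"}:
        raise ValueError(f"mitochondrial chromosome {name!r} is not supported")
    return "autosome"


def read_bed(path: str | Path, check_sorted: bool = False) -> pd.DataFrame:
    """Read a 3+ column BED file into a DataFrame (chrom, start, end[, name]).

    Raises ``ValueError`` naming the offending line for non-integer or
    inverted coordinates.
    """
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: require 0 <= start < end, got {start}..{end}")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, name))
    bed = pd.DataFrame(rows, columns=BED_COLUMNS)
    if check_sorted:
        key = bed[["chrom", "start"]].apply(tuple, axis=1).tolist()
        if key != sorted(key):
            raise ValueError(f"{path}: intervals are not sorted by (chrom, start)")
    return bed


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in bed.columns]
    bed[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an OCR-by-sample count matrix (first column = OCR id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="ocr_id")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, then gene ids, tab-delimited."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            sets[parts[0]] = set(parts[2:])
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Read a bin-pair contact table with columns (chrom, bin_i, bin_j, freq)."""
    contacts = pd.read_csv(path, sep="\t")
    required = {"chrom", "bin_i", "bin_j", "freq"}
    if not required.issubset(contacts.columns):
        raise ValueError(f"{path}: contact table needs columns {sorted(required)}")
    if (contacts["freq"] < 0).any():
        raise ValueError(f"{path}: negative contact frequencies")
    return contacts


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Checksums and provenance of one pipeline run.

    Re-running with an identical config and inputs reproduces identical
    checksums for every deterministic stage.
    """

    version: str
    config_hash: str
    files: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def collect(cls, version: str, cfg: dict, paths: list[Path]) -> "RunManifest":
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        files = {str(p): _sha256(Path(p)) for p in paths if Path(p).is_file()}
        return cls(version=version, config_hash=cfg_hash, files=files,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def diff(self, other: "RunManifest") -> list[str]:
        """Names of files whose checksums differ (or are missing) between runs."""
        keys = set(self.files) | set(other.files)
        return sorted(k for k in keys if self.files.get(k) != other.files.get(k))
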