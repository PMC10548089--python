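"""Shared I/O, run configuration and seeded RNG plumbing.

Gene identifiers are opaque, case-sensitive strings throughout the
pipeline; no attempt is made to reconcile different gene-model catalogues
(NVE vs NV2 style ids) — callers may supply a two-column mapping file and
translate ids before any set operation.

All output tables are single-header TSV with a sidecar JSON of run
metadata so that every result is diff-able and self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from .target_scan import ScanParams

logger = logging.getLogger("cnidomir")

__all__ = [
    "GeneSet",
    "RunConfig",
    "read_gene_set",
    "write_gene_set",
    "read_mapping",
    "read_fasta",
    "write_fasta",
    "load_config",
    "write_run_metadata",
    "derive_rng",
]

_VALID_SEQ_CHARS = set("ACGTUNacgtun")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of distinct gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        for g in self.members:
            if not g or g != g.strip():
                raise ValueError(f"gene set {self.name!r}: blank or untrimmed id {g!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(self.members)

    def intersection(self, other: "GeneSet | Iterable[str]") -> frozenset[str]:
        other_members = other.members if isinstance(other, GeneSet) else frozenset(other)
        return self.members & other_members


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and reproducibility settings.

    Defaults mirror the study design: 10,000 permutation replicates,
    DEGs at FDR < 0.05 with fold change >= 2, and background genes
    required to reach 1 CPM in all but one library (genes below 1 CPM
    in at least two libraries are removed).
    """

    seed: int = 0
    permutations: int = 10_000
    fdr_threshold: float = 0.05
    fold_change_threshold: float = 2.0
    cpm_threshold: float = 1.0
    cpm_min_libraries: int = 2
    scan: ScanParams = field(default_factory=ScanParams)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        for name in ("fdr_threshold", "fold_change_threshold", "cpm_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cpm_min_libraries < 1:
            raise ValueError("cpm_min_libraries must be >= 1")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from one-id-per-line text or two-column TSV.

    In the two-column form the first column is the set name and the
    second the gene id; the name of the first row wins. Duplicate ids
    are dropped with a warning.
    """
    path = Path(path)
    members: list[str] = []
    seen: set[str] = set()
    n_dupes = 0
    set_name = name
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 2:
                if set_name is None:
                    set_name = fields[0]
                gene = fields[1].strip()
            else:
                gene = fields[0].strip()
            if not gene:
                continue
            if gene in seen:
                n_dupes += 1
                continue
            seen.add(gene)
            members.append(gene)
    if not members:
        raise ValueError(f"empty gene set: {path}")
    if n_dupes:
        logger.warning("%s: dropped %d duplicate gene ids", path, n_dupes)
    return GeneSet(name=set_name or path.stem, members=frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """Write one id per line, sorted for stable diffs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gene in sorted(gene_set.members):
            fh.write(gene + "\n")


def read_mapping(path: str | Path) -> dict[str, str]:
    """Optional two-column (from-id, to-id) translation table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            src, dst = line.split("\t")[:2]
            mapping[src.strip()] = dst.strip()
    return mapping


def _prevalidate_fasta(path: Path) -> None:
    """Line-scan for the error contract: malformed headers or illegal
    sequence characters are reported with their line number."""
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if len(line) < 2 or not line[1:].strip():
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                saw_header = True
                continue
            if not saw_header:
                raise ValueError(f"{path}:{lineno}: sequence before first FASTA header")
            bad = set(line) - _VALID_SEQ_CHARS
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: illegal sequence character(s) "
                    f"{''.join(sorted(bad))!r} (alphabet is ACGTUN)"
                )
    if not saw_header:
        raise ValueError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path, alphabet: str = "rna") -> list:
    """Read FASTA records, normalizing case and the T/U alphabet.

    Both DNA (T) and RNA (U) input are accepted; sequences are
    uppercased and converted to the requested internal alphabet
    (``rna`` by default, matching how duplexes are reported).
    Returns Biopython ``SeqRecord`` objects in input order.
    """
    from Bio.Seq import Seq

    path = Path(path)
    _prevalidate_fasta(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    for rec in records:
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            seq = seq.replace("T", "U")
        elif alphabet == "dna":
            seq = seq.replace("U", "T")
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        rec.seq = Seq(seq)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_CONFIG_KEYS = {
    "seed",
    "permutations",
    "fdr_threshold",
    "fold_change_threshold",
    "cpm_threshold",
    "cpm_min_libraries",
    "scan",
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; unspecified keys take defaults.

    The effective configuration is echoed to the log so every run is
    self-documenting; pair with :func:`write_run_metadata` to persist
    it next to the outputs.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(_CONFIG_KEYS)}"
        )
    scan_data = data.pop("scan", {}) or {}
    scan_fields = {f.name for f in dataclasses.fields(ScanParams)}
    unknown_scan = set(scan_data) - scan_fields
    if unknown_scan:
        raise ValueError(
            f"unknown scan key(s) {sorted(unknown_scan)}; valid keys: {sorted(scan_fields)}"
        )
    for key, value in data.items():
        if key in ("seed", "permutations", "cpm_min_libraries"):
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValueError(f"config key {key!r} must be an integer, got {value!r}")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"config key {key!r} must be numeric, got {value!r}")
    cfg = RunConfig(scan=ScanParams(**scan_data), **data)
    logger.info("effective config: %s", config_to_dict(cfg))
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def write_run_metadata(out_dir: str | Path, cfg: RunConfig, **extra) -> Path:
    """Write the effective configuration (plus any stage-specific
    details) as a JSON sidecar for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config_to_dict(cfg), **extra}
    path = out_dir / "run_metadata.json"
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def derive_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream.

    One process-wide seed fans out into independent child streams, one
    per named stage, so that adding replicates to one stage never
    perturbs another.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    stage_key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, stage_key]))
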