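"""Standard-format I/O and shared sequence utilities.

FASTA/FASTQ parsing is delegated to Bio.SeqIO; Newick to skbio.TreeNode.
Also hosts the small sequence primitives the whole pipeline shares:
reverse complement, canonical rotation (satellite monomers have arbitrary
phase and strand), gap-tolerant percent identity (edlib), and per-component
seeded RNG derivation.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


@dataclass
class SeqRecordSimple:
    """One sequence record: id, uppercase ACGTN sequence, optional quality."""

    id: str
    sequence: str
    quality: str | None = None


class MalformedRecordError(ValueError):
    pass


def _normalize(seq: str, idx: int, rid: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise MalformedRecordError(
            f"record {idx} ({rid!r}): invalid characters {sorted(bad)}"
        )
    return s


def read_sequences(path, fmt: str = "fasta") -> list[SeqRecordSimple]:
    """Read FASTA or FASTQ records; sequences uppercased, ACGTN only, order kept."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {fmt}")
    out: list[SeqRecordSimple] = []
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise MalformedRecordError(f"record {len(out)}: {exc}") from exc
    for i, rec in enumerate(records):
        seq = _normalize(str(rec.seq), i, rec.id)
        qual = None
        if fmt == "fastq":
            phred = rec.letter_annotations.get("phred_quality")
            if phred is not None:
                qual = "".join(chr(q + 33) for q in phred)
        out.append(SeqRecordSimple(id=rec.id, sequence=seq, quality=qual))
    return out


def write_sequences(path, records: Iterable[SeqRecordSimple], fmt: str = "fasta") -> None:
    recs = []
    for r in records:
        br = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "fastq":
            qual = r.quality or "I" * len(r.sequence)
            br.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        recs.append(br)
    SeqIO.write(recs, str(path), fmt)


def write_newick(tree: TreeNode) -> str:
    """Serialise a rooted tree to Newick with branch lengths.

    Raises on duplicate leaf labels. A single-leaf tree is rejected
    (degenerate; no topology to serialise).
    """
    tips = [t.name for t in tree.tips()] or [tree.name]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels")
    if len(tips) < 2:
        raise ValueError("single-leaf tree has no serialisable topology")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


# --- sequence primitives -------------------------------------------------


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def min_rotation(s: str) -> str:
    """Lexicographically smallest rotation of s (monomers are circular)."""
    if not s:
        return s
    d = s + s
    return min(d[i : i + len(s)] for i in range(len(s)))


def canonical_rotation(s: str) -> str:
    """Smallest rotation over both strands: the package-wide phase convention."""
    if not s:
        return s
    return min(min_rotation(s), min_rotation(revcomp(s)))


def identity_percent(a: str, b: str) -> float:
    """Gap-tolerant global percent identity: 100·(1 − editdist/max(len))."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def rotated_identity_percent(a: str, b: str) -> float:
    """Rotation/strand-invariant percent identity between circular sequences.

    The shorter sequence is matched as an infix of the doubled longer one
    (both strands), so monomer phase cannot depress the score; a lexical
    canonical-rotation anchor would be unstable under point mutation.
    """
    if not a or not b:
        return 0.0
    if len(a) > len(b):
        a, b = b, a
    doubled = b + b
    d = min(
        edlib.align(a, doubled, mode="HW", task="distance")["editDistance"],
        edlib.align(revcomp(a), doubled, mode="HW", task="distance")["editDistance"],
    )
    # infix matching absorbs length differences; charge them back
    d += len(b) - len(a)
    return 100.0 * (1.0 - d / len(b))


def majority_consensus(rows: Sequence[str]) -> str:
    """Per-column majority base over equal-length strings ('-' columns dropped)."""
    if not rows:
        return ""
    L = len(rows[0])
    out = []
    for j in range(L):
        counts: dict[str, int] = {}
        for r in rows:
            c = r[j] if j < len(r) else "-"
            counts[c] = counts.get(c, 0) + 1
        best = max(sorted(counts), key=lambda c: counts[c])
        if best != "-":
            out.append(best)
    return "".join(out)


def derive_seed(root_seed: int, *parts) -> int:
    """Stable per-component RNG seed < 2^31 from a root seed and labels."""
    h = hashlib.sha256(repr((int(root_seed),) + tuple(parts)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(root_seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, *parts))


# --- tabular + config ----------------------------------------------------


def write_tsv(path, rows: list[dict], columns: list[str]) -> None:
    """Single tabular dialect: tab-separated, header row, '.' for missing."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "." if row.get(c) is None else str(row.get(c)) for c in columns
                )
                + "\n"
            )


def read_tsv(path) -> list[dict]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rows.append(
                {h: (None if v == "." else v) for h, v in zip(header, vals)}
            )
    return rows


@dataclass
class PipelineConfig:
    """Effective configuration for a pipeline run; CLI flags override file values."""

    seed: int = 0
    output_dir: str = "satfam_out"
    log_level: str = "INFO"
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {k: v for k, v in data.items() if k in ("seed", "output_dir", "log_level")}
        cfg = cls(**known)
        cfg.stage_params = data.get("stage_params", {})
        cfg.seed = int(cfg.seed)
        return cfg

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "output_dir": self.output_dir,
                "log_level": self.log_level,
                "stage_params": self.stage_params,
            },
            indent=2,
        )
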