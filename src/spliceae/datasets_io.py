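"""FASTA/BED ingestion and fixed-length splice-site window construction.

Splice sites are anchored by their 2-nt consensus dinucleotide (intron-
terminal ``AG`` for acceptors, intron-initial ``GT`` for donors). Windows
of a fixed length L (90 nt acceptor / 15 nt donor by default) are placed so
that the anchor occupies the two central positions, window indices
``L//2 - 1`` and ``L//2``. Minus-strand sites are reverse-complemented
before windowing, so the anchor reads in its 5'->3' orientation.

Coordinates are 0-based half-open internally (BED convention); only
user-facing reports are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

__all__ = [
    "SequenceWindow",
    "SiteAnnotation",
    "DatasetSplit",
    "ANCHORS",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "reverse_complement",
    "anchor_index",
    "extract_windows",
    "window_anchor_start",
    "make_negatives",
    "split_train_validation",
    "windows_to_tsv",
    "windows_from_tsv",
]

logger = logging.getLogger(__name__)

ANCHORS = {"acceptor": "AG", "donor": "GT"}
DEFAULT_WINDOW = {"acceptor": 90, "donor": 15}


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length genomic window anchored on a splice dinucleotide."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    site_type: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("sequence length != end - start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class SiteAnnotation:
    """A BED-style annotated site (anchor interval)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"bad interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class DatasetSplit:
    train: list[SequenceWindow]
    validation: list[SequenceWindow]
    seed: int


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read a multi-FASTA into an ordered ``{id: sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str, width: int = 60) -> None:
    """Write an ``{id: sequence}`` mapping as wrapped multi-FASTA."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_bed(path: str) -> list[SiteAnnotation]:
    """Read BED3+ annotations (optional name/score/strand columns)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype=str
    )
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom, start, end")
    sites = []
    for row in df.itertuples(index=False):
        vals = list(row) + ["."] * (6 - len(row))
        strand = vals[5] if vals[5] in "+-" else "+"
        sites.append(
            SiteAnnotation(
                vals[0], int(vals[1]), int(vals[2]), vals[3], vals[4], strand
            )
        )
    return sites


def write_bed(sites: Sequence[SiteAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.name}\t{s.score}\t{s.strand}\n"
            )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def anchor_index(window_len: int, offset: int | None = None) -> int:
    """0-based window index of the anchor's first base (central placement
    unless an explicit offset is configured)."""
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    idx = window_len // 2 - 1 if offset is None else offset
    if not 0 <= idx <= window_len - 2:
        raise ValueError(f"anchor offset {idx} outside window of {window_len}")
    return idx


def extract_windows(
    genome: Mapping[str, str],
    sites: Sequence[SiteAnnotation],
    site_type: str,
    window_len: int | None = None,
    *,
    offset: int | None = None,
) -> tuple[list[SequenceWindow], int]:
    """Extract labelled (label=1) windows around annotated anchors.

    Plus-strand: window indices ``c, c+1`` (``c = window_len//2 - 1``) hold
    the anchor. Minus-strand: the genomic slice is chosen so the reverse
    complement carries the anchor at the same indices. Sites whose window
    would run off the sequence are skipped; returns ``(windows, n_skipped)``.
    """
    if site_type not in ANCHORS:
        raise ValueError(f"unknown site_type {site_type!r}")
    L = DEFAULT_WINDOW[site_type] if window_len is None else window_len
    c = anchor_index(L, offset)
    windows: list[SequenceWindow] = []
    skipped = 0
    for site in sites:
        seq = genome.get(site.chrom)
        if seq is None:
            skipped += 1
            continue
        a = site.start  # anchor first base, 0-based
        if site.strand == "+":
            w_start = a - c
            w_end = w_start + L
        else:
            w_end = a + c + 2
            w_start = w_end - L
        if w_start < 0 or w_end > len(seq):
            skipped += 1
            continue
        sub = seq[w_start:w_end]
        if site.strand == "-":
            sub = reverse_complement(sub)
        windows.append(
            SequenceWindow(
                site.chrom, w_start, w_end, site.strand, site_type, sub, 1
            )
        )
    if skipped:
        logger.info("extract_windows: skipped %d out-of-range sites", skipped)
    return windows, skipped


def window_anchor_start(
    window: SequenceWindow, offset: int | None = None
) -> int:
    """Map a window back to its anchor's 0-based genomic start (inverse of
    the placement rule, both strands)."""
    c = anchor_index(window.end - window.start, offset)
    if window.strand == "+":
        return window.start + c
    return window.end - c - 2


# ---------------------------------------------------------------------------
# Negatives
# ---------------------------------------------------------------------------

def _positive_anchor_set(sites: Sequence[SiteAnnotation]) -> set[tuple[str, int]]:
    occupied = set()
    for s in sites:
        for pos in range(s.start, s.end):
            occupied.add((s.chrom, pos))
    return occupied


def make_negatives(
    genome: Mapping[str, str],
    sites: Sequence[SiteAnnotation],
    site_type: str,
    window_len: int | None = None,
    *,
    policy: str = "decoy",
    ratio: float = 1.0,
    seed: int = 0,
    offset: int | None = None,
) -> list[SequenceWindow]:
    """Construct label-0 windows that do not overlap any positive anchor.

    ``policy="decoy"`` centres windows on unannotated occurrences of the
    anchor dinucleotide (hard negatives); ``policy="random"`` uses uniform
    non-site positions. ``ratio`` scales the count relative to the number
    of annotated sites. Seeded and deterministic.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if site_type not in ANCHORS:
        raise ValueError(f"unknown site_type {site_type!r}")
    L = DEFAULT_WINDOW[site_type] if window_len is None else window_len
    c = anchor_index(L, offset)
    anchor = ANCHORS[site_type]
    occupied = _positive_anchor_set(sites)

    candidates: list[tuple[str, int]] = []
    for chrom, seq in genome.items():
        lo, hi = c, len(seq) - (L - c)  # anchor start range keeping window in
        for a in range(lo, hi + 1):
            if (chrom, a) in occupied or (chrom, a + 1) in occupied:
                continue
            if policy == "decoy":
                if seq[a : a + 2] != anchor:
                    continue
            elif policy != "random":
                raise ValueError(f"unknown policy {policy!r}")
            candidates.append((chrom, a))

    n_needed = int(round(ratio * len(sites)))
    if n_needed > len(candidates):
        raise ValueError(
            f"only {len(candidates)} candidate negatives for {n_needed} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    negatives = []
    for i in sorted(chosen):
        chrom, a = candidates[i]
        w_start = a - c
        negatives.append(
            SequenceWindow(
                chrom, w_start, w_start + L, "+", site_type,
                genome[chrom][w_start : w_start + L], 0,
            )
        )
    return negatives


# ---------------------------------------------------------------------------
# Train/validation split
# ---------------------------------------------------------------------------

def split_train_validation(
    windows: Sequence[SequenceWindow],
    n_validation: int = 5000,
    seed: int = 0,
) -> DatasetSplit:
    """Seeded stratified draw of ``n_validation`` windows for validation;
    the rest train. Disjoint and exhaustive."""
    windows = list(windows)
    if n_validation >= len(windows):
        raise ValueError(
            f"n_validation={n_validation} >= dataset size {len(windows)}"
        )
    labels = [w.label for w in windows]
    train, val = train_test_split(
        windows,
        test_size=n_validation,
        stratify=labels,
        random_state=seed % (2**32),
        shuffle=True,
    )
    return DatasetSplit(list(train), list(val), seed)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

_TSV_COLS = ["chrom", "start", "end", "strand", "site_type", "label", "sequence"]


def windows_to_tsv(windows: Sequence[SequenceWindow], path: str) -> None:
    df = pd.DataFrame(
        [
            (w.chrom, w.start, w.end, w.strand, w.site_type, w.label, w.sequence)
            for w in windows
        ],
        columns=_TSV_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def windows_from_tsv(path: str) -> list[SequenceWindow]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SequenceWindow(
            str(r.chrom), int(r.start), int(r.end), r.strand, r.site_type,
            r.sequence, int(r.label),
        )
        for r in df.itertuples(index=False)
    ]
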