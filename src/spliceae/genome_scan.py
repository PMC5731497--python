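"""Sliding-window scanning of arbitrary sequence with a trained network.

Every window start (stride ``step``) is encoded under the model's scheme
and scored; windows at or above the probability threshold emit a
``SpliceSiteCall`` at the anchor's 1-based coordinate. Overlapping calls
are thinned by greedy non-maximum suppression, and calls are written as
BED6 over the 2-nt anchor interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import StackedNetwork, predict_proba
from .datasets_io import SiteAnnotation, anchor_index, write_bed
from .encodings import EncodingScheme, encode_sequence

__all__ = ["SpliceSiteCall", "scan", "suppress", "write_calls", "read_calls"]

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SpliceSiteCall:
    """A scored site nomination; ``position`` is the 1-based coordinate of
    the anchor's first base."""

    chrom: str
    position: int
    strand: str
    site_type: str
    score: float


def scan(
    network: StackedNetwork,
    scheme: EncodingScheme,
    record: tuple[str, str],
    site_type: str,
    *,
    step: int = 1,
    threshold: float = 0.5,
    strand: str = "+",
    offset: int | None = None,
) -> list[SpliceSiteCall]:
    """Score every window of ``record = (name, sequence)`` and nominate
    sites.

    The window length is inferred from the network input width and the
    scheme arity. Windows containing non-ACGT characters are skipped (their
    count is logged). Calls come back sorted by position.
    """
    name, seq = record
    seq = seq.upper().replace("U", "T")
    window_len = network.d_input + (scheme.arity - 1)
    c = anchor_index(window_len, offset)
    if len(seq) < window_len:
        logger.warning(
            "sequence %s shorter (%d) than window (%d); no calls",
            name, len(seq), window_len,
        )
        return []

    starts, rows = [], []
    n_skipped = 0
    for s in range(0, len(seq) - window_len + 1, step):
        sub = seq[s : s + window_len]
        if not _VALID.issuperset(sub):
            n_skipped += 1
            continue
        starts.append(s)
        rows.append(encode_sequence(sub, scheme))
    if n_skipped:
        logger.info("scan: skipped %d windows with ambiguity codes", n_skipped)
    if not starts:
        return []
    probs = predict_proba(network, np.vstack(rows))
    calls = [
        SpliceSiteCall(name, s + c + 1, strand, site_type, float(p))
        for s, p in zip(starts, probs)
        if p >= threshold
    ]
    return sorted(calls, key=lambda call: call.position)


def suppress(calls: list[SpliceSiteCall], radius: int) -> list[SpliceSiteCall]:
    """Greedy non-maximum suppression: repeatedly keep the highest-scoring
    remaining call (ties -> leftmost) and drop every call within ``radius``
    nt of it. Returns the survivors sorted by position."""
    remaining = sorted(calls, key=lambda c: (-c.score, c.position))
    kept: list[SpliceSiteCall] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            c for c in remaining
            if c.chrom != best.chrom or abs(c.position - best.position) > radius
        ]
    return sorted(kept, key=lambda c: (c.chrom, c.position))


def write_calls(calls: list[SpliceSiteCall], path: str) -> None:
    """Write calls as BED6 over the 2-nt anchor (0-based half-open); score
    column is ``round(1000 * probability)``."""
    sites = [
        SiteAnnotation(
            c.chrom, c.position - 1, c.position + 1,
            c.site_type, str(int(round(1000 * c.score))), c.strand,
        )
        for c in calls
    ]
    write_bed(sites, path)


def read_calls(path: str) -> list[SpliceSiteCall]:
    """Read back a BED6 call file written by :func:`write_calls`."""
    from .datasets_io import read_bed

    calls = []
    for s in read_bed(path):
        calls.append(
            SpliceSiteCall(
                s.chrom, s.start + 1, s.strand, s.name,
                float(s.score) / 1000.0,
            )
        )
    return calls
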