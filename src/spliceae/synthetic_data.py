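"""Synthetic splice-site window datasets and small genomes with planted
sites.

Positives carry the site's consensus anchor dinucleotide (``AG`` acceptor,
``GT`` donor) at the central window placement, flanked by bases drawn from
a position-weight matrix (PWM); everything else is background composition.
Negatives are background throughout; *decoy* negatives additionally carry
the anchor dinucleotide at the centre, so they can only be told apart from
positives by their flanks. The default PWM puts 0.7 probability on one
consensus base per flank position (cycling A,C,G,T) and 0.1 on the others —
a strong but not trivial signal over the uniform background. With a uniform
PWM positives and decoy negatives are statistically identical, which drives
trained accuracy to chance; the PWM information content is therefore the
dial between a separable and an unlearnable problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import (
    ANCHORS,
    DEFAULT_WINDOW,
    SequenceWindow,
    SiteAnnotation,
    anchor_index,
)

__all__ = [
    "MotifModel",
    "default_pwm",
    "sample_positive",
    "sample_negative",
    "generate_dataset",
    "plant_genome",
]

_BASES = "ACGT"


def default_pwm(width: int, strength: float = 0.7) -> np.ndarray:
    """(width x 4) PWM with ``strength`` on a per-position consensus base
    (cycling A,C,G,T) and the remainder split over the other three."""
    pwm = np.full((width, 4), (1.0 - strength) / 3.0)
    for i in range(width):
        pwm[i, i % 4] = strength
    return pwm


@dataclass
class MotifModel:
    """Generative model for splice-site windows.

    ``pwm`` has ``2 * flank`` rows: rows ``0..flank-1`` describe positions
    immediately left of the anchor (row ``flank-1`` adjacent to it), rows
    ``flank..2*flank-1`` the positions to its right. Flanks are clipped at
    the window edge.
    """

    site_type: str = "acceptor"
    window_len: int | None = None
    flank: int = 10
    pwm: np.ndarray | None = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_type not in ANCHORS:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.window_len is None:
            self.window_len = DEFAULT_WINDOW[self.site_type]
        if self.pwm is None:
            self.pwm = default_pwm(2 * self.flank)
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.shape != (2 * self.flank, 4):
            raise ValueError("pwm must have shape (2*flank, 4)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def consensus(self) -> str:
        return ANCHORS[self.site_type]

    @property
    def anchor_pos(self) -> int:
        return anchor_index(self.window_len)


def _draw(probs: np.ndarray, rng: np.random.Generator) -> str:
    return _BASES[rng.choice(4, p=probs)]


def _window_string(
    model: MotifModel, rng: np.random.Generator, planted: bool
) -> str:
    L, c = model.window_len, model.anchor_pos
    chars = [_draw(model.background, rng) for _ in range(L)]
    if planted:
        # PWM flanks, clipped at the window edges
        left = min(model.flank, c)
        for j in range(left):
            pos = c - left + j
            row = model.flank - left + j
            chars[pos] = _draw(model.pwm[row], rng)
        right = min(model.flank, L - c - 2)
        for j in range(right):
            chars[c + 2 + j] = _draw(model.pwm[model.flank + j], rng)
    return "".join(chars)


def sample_positive(
    model: MotifModel, rng: np.random.Generator
) -> SequenceWindow:
    """One label-1 window: consensus anchor at the centre, PWM flanks,
    background elsewhere."""
    s = _window_string(model, rng, planted=True)
    c = model.anchor_pos
    s = s[:c] + model.consensus + s[c + 2 :]
    return SequenceWindow(
        "synthetic", 0, model.window_len, "+", model.site_type, s, 1
    )


def sample_negative(
    model: MotifModel, rng: np.random.Generator, decoy: bool = False
) -> SequenceWindow:
    """One label-0 window: pure background; ``decoy`` plants the anchor
    dinucleotide at the centre with background flanks."""
    s = _window_string(model, rng, planted=False)
    if decoy:
        c = model.anchor_pos
        s = s[:c] + model.consensus + s[c + 2 :]
    return SequenceWindow(
        "synthetic", 0, model.window_len, "+", model.site_type, s, 0
    )


def generate_dataset(
    n_pos: int,
    n_neg: int,
    model: MotifModel,
    *,
    decoy_fraction: float = 0.0,
) -> list[SequenceWindow]:
    """Seeded labelled dataset of ``n_pos`` positives and ``n_neg``
    negatives, deterministically shuffled.

    Negatives default to pure background (``sample_negative``'s default);
    raise ``decoy_fraction`` to make that share of them centre-anchored
    decoys, which hardens the task."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(model.seed)
    n_decoy = int(round(decoy_fraction * n_neg))
    windows = [sample_positive(model, rng) for _ in range(n_pos)]
    windows += [
        sample_negative(model, rng, decoy=i < n_decoy) for i in range(n_neg)
    ]
    order = rng.permutation(len(windows))
    return [windows[i] for i in order]


def plant_genome(
    length: int,
    site_positions: list[int],
    model: MotifModel,
) -> tuple[dict[str, str], list[SiteAnnotation]]:
    """Background genome of ``length`` nt with positive windows overwritten
    at the given 0-based anchor starts.

    Returns ``({chrom: sequence}, annotations)``; the annotations round-trip
    through ``extract_windows`` to sequences identical to the planted
    windows. Raises on overlapping or out-of-range plants.
    """
    L, c = model.window_len, model.anchor_pos
    rng = np.random.default_rng(model.seed)
    positions = sorted(site_positions)
    prev_end = -1
    for a in positions:
        w_start, w_end = a - c, a - c + L
        if w_start < 0 or w_end > length:
            raise ValueError(f"planted window at anchor {a} out of range")
        if w_start < prev_end:
            raise ValueError("overlapping planted windows")
        prev_end = w_end
    chars = list(
        "".join(_draw(model.background, rng) for _ in range(length))
    )
    annotations = []
    for a in positions:
        win = sample_positive(model, rng)
        chars[a - c : a - c + L] = win.sequence
        annotations.append(
            SiteAnnotation(
                "synthetic_chr", a, a + 2, model.site_type, ".", "+"
            )
        )
    return {"synthetic_chr": "".join(chars)}, annotations
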