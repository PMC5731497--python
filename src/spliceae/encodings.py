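"""Numeric encoding schemes for DNA sequences.

Five schemes from the splice-site prediction literature are shipped as
defaults, each mapping mono- or di-nucleotides over {A,C,G,T} to real values:

``dax``
    An integer rank code (T=0, C=1, A=2, G=3).
``eiip``
    Electron-ion interaction potential per nucleotide (Nair & Sreenadhan
    pseudo-potentials).
``complementary``
    Signed code in which Watson-Crick complements map to negations
    (A=-2/T=+2, C=-1/G=+1), so the reverse complement of a sequence encodes
    to the negated reverse of its encoding.
``enthalpy``
    Nearest-neighbour dinucleotide stacking enthalpies (ΔH, kcal/mol) from
    the unified thermodynamic parameter set; a di-nucleotide scheme, so a
    sequence of length L encodes to L-1 values.
``galois4``
    The four elements of GF(4) as integer labels (A=0, C=1, G=2, T=3).

All schemes are by default affinely rescaled to [0, 1] so that sigmoid
reconstruction layers can model them; pass ``scale=None`` for raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "EncodingScheme",
    "SCHEME_NAMES",
    "build_scheme",
    "encode_sequence",
    "encode_batch",
    "scheme_to_config",
    "scheme_from_config",
]

_MONO = "ACGT"
_DI = tuple(a + b for a in _MONO for b in _MONO)

# Default numeric tables (Fig.-style literature values, override via
# build_scheme(..., overrides=...) or a config file).
_DAX = {"T": 0.0, "C": 1.0, "A": 2.0, "G": 3.0}
_EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}
_COMPLEMENTARY = {"A": -2.0, "T": 2.0, "C": -1.0, "G": 1.0}
_GALOIS4 = {"A": 0.0, "C": 1.0, "G": 2.0, "T": 3.0}
# Unified nearest-neighbour DNA duplex formation enthalpies, kcal/mol.
_ENTHALPY = {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0,
}

_DEFAULTS: dict[str, tuple[str, dict[str, float]]] = {
    "dax": ("mono", _DAX),
    "eiip": ("mono", _EIIP),
    "complementary": ("mono", _COMPLEMENTARY),
    "enthalpy": ("di", _ENTHALPY),
    "galois4": ("mono", _GALOIS4),
}

SCHEME_NAMES = tuple(_DEFAULTS)

_ALIASES = {"comp": "complementary", "galois": "galois4", "gf4": "galois4"}


@dataclass(frozen=True)
class EncodingScheme:
    """A named lookup table turning DNA into numeric vectors.

    Parameters
    ----------
    name : str
        One of the packaged scheme names, or ``"custom"``.
    unit : str
        ``"mono"`` (4 single-base keys) or ``"di"`` (16 dinucleotide keys).
    table : mapping
        Key -> real value, total over the declared alphabet.
    scale : tuple or None
        ``(lo, hi)`` range the table's min/max are affinely mapped onto,
        or ``None`` to emit raw table values.
    """

    name: str
    unit: str
    table: Mapping[str, float]
    scale: tuple[float, float] | None = (0.0, 1.0)

    def __post_init__(self) -> None:
        keys = _MONO if self.unit == "mono" else _DI
        if self.unit not in ("mono", "di"):
            raise ValueError(f"unit must be 'mono' or 'di', got {self.unit!r}")
        missing = [k for k in keys if k not in self.table]
        if missing:
            raise ValueError(
                f"scheme {self.name!r} table incomplete: missing {missing}"
            )
        extra = [k for k in self.table if k not in keys]
        if extra:
            raise ValueError(f"scheme {self.name!r} has unknown keys {extra}")
        vals = np.asarray([self.table[k] for k in keys], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"scheme {self.name!r} has non-finite table values")

    @property
    def arity(self) -> int:
        """Lookup-key length: 1 for mono, 2 for di schemes."""
        return 1 if self.unit == "mono" else 2

    def output_length(self, seq_len: int) -> int:
        """Encoded-vector length for a sequence of ``seq_len`` bases."""
        return seq_len - (self.arity - 1)


def build_scheme(
    name: str,
    overrides: Mapping[str, float] | None = None,
    *,
    unit: str | None = None,
    scale: tuple[float, float] | None = (0.0, 1.0),
) -> EncodingScheme:
    """Construct a packaged scheme by name, optionally overriding entries.

    ``name="custom"`` requires a complete ``overrides`` table plus ``unit``.
    Deterministic: no randomness anywhere in scheme construction.
    """
    key = _ALIASES.get(name.lower(), name.lower())
    if key == "custom":
        if unit is None:
            raise ValueError("custom scheme requires unit='mono' or 'di'")
        table = dict(overrides or {})
        return EncodingScheme("custom", unit, table, scale)
    if key not in _DEFAULTS:
        raise ValueError(
            f"unknown encoding scheme {name!r}; known: {sorted(_DEFAULTS)}"
        )
    default_unit, default_table = _DEFAULTS[key]
    table = dict(default_table)
    if overrides:
        bad = [k for k in overrides if k not in table]
        if bad:
            raise ValueError(f"override keys {bad} not in {key!r} alphabet")
        table.update({k: float(v) for k, v in overrides.items()})
    return EncodingScheme(key, default_unit, table, scale)


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def encode_sequence(
    seq: str,
    scheme: EncodingScheme,
    *,
    ambiguity: str = "reject",
) -> np.ndarray:
    """Encode one DNA string into a numeric vector under ``scheme``.

    Output value ``i`` is ``table[seq[i]]`` (mono) or ``table[seq[i:i+2]]``
    (di); length is ``L`` or ``L-1`` respectively. Lower case and RNA ``U``
    are accepted. Characters outside {A,C,G,T} follow the ``ambiguity``
    policy: ``"reject"`` raises, ``"impute"`` substitutes the table mean.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    s = _clean(seq)
    if len(s) < scheme.arity:
        raise ValueError(
            f"sequence of length {len(s)} too short for {scheme.unit} scheme"
        )
    if ambiguity not in ("reject", "impute"):
        raise ValueError(f"unknown ambiguity policy {ambiguity!r}")

    table = scheme.table
    mean = float(np.mean(list(table.values())))
    units: Iterable[str]
    if scheme.unit == "mono":
        units = s
    else:
        units = (s[i : i + 2] for i in range(len(s) - 1))

    out = np.empty(scheme.output_length(len(s)), dtype=float)
    for i, u in enumerate(units):
        v = table.get(u)
        if v is None:
            if ambiguity == "reject":
                raise ValueError(f"ambiguous/unknown unit {u!r} at position {i}")
            v = mean
        out[i] = v
    return _rescale(out, scheme)


def _rescale(values: np.ndarray, scheme: EncodingScheme) -> np.ndarray:
    if scheme.scale is None:
        return values
    lo, hi = scheme.scale
    tvals = np.asarray(list(scheme.table.values()), dtype=float)
    tmin, tmax = tvals.min(), tvals.max()
    if tmax == tmin:  # degenerate table: map everything to the midpoint
        return np.full_like(values, (lo + hi) / 2.0)
    return lo + (values - tmin) * (hi - lo) / (tmax - tmin)


def encode_batch(
    windows: Sequence,
    scheme: EncodingScheme,
    *,
    window_len: int | None = None,
    ambiguity: str = "reject",
) -> tuple[np.ndarray, np.ndarray]:
    """Encode equal-length windows into a matrix plus aligned label vector.

    ``windows`` items are either ``SequenceWindow``-like objects (with
    ``.sequence`` and ``.label``) or plain ``(sequence, label)`` pairs.
    Row order is preserved. For an empty batch ``window_len`` declares the
    matrix width.
    """
    seqs: list[str] = []
    labels: list[int] = []
    for w in windows:
        if hasattr(w, "sequence"):
            seqs.append(w.sequence)
            labels.append(int(getattr(w, "label", 0)))
        else:
            s, y = w
            seqs.append(s)
            labels.append(int(y))

    if not seqs:
        if window_len is None:
            raise ValueError("empty batch requires window_len to fix the width")
        width = scheme.output_length(window_len)
        return np.empty((0, width), dtype=float), np.empty(0, dtype=int)

    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths in batch: {sorted(lengths)}")
    if window_len is not None and lengths != {window_len}:
        raise ValueError(
            f"windows have length {lengths.pop()}, expected {window_len}"
        )
    X = np.vstack(
        [encode_sequence(s, scheme, ambiguity=ambiguity) for s in seqs]
    )
    return X, np.asarray(labels, dtype=int)


def scheme_to_config(scheme: EncodingScheme, path: str) -> None:
    """Serialize a scheme to a flat key-value YAML file."""
    doc = {
        "name": scheme.name,
        "unit": scheme.unit,
        "scale": list(scheme.scale) if scheme.scale is not None else None,
        **{f"table.{k}": float(v) for k, v in sorted(scheme.table.items())},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scheme_from_config(path: str) -> EncodingScheme:
    """Load a scheme written by :func:`scheme_to_config`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    table = {
        k.split(".", 1)[1]: float(v)
        for k, v in doc.items()
        if k.startswith("table.")
    }
    scale = doc.get("scale")
    return EncodingScheme(
        doc["name"],
        doc["unit"],
        table,
        tuple(scale) if scale is not None else None,
    )


def with_scale(
    scheme: EncodingScheme, scale: tuple[float, float] | None
) -> EncodingScheme:
    """Return a copy of ``scheme`` with a different output range."""
    return replace(scheme, scale=scale)
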