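"""Multi-hot condition vectors for H₂-mediated reactions.

A reaction condition is encoded as a fixed-layout bitstring with four blocks,
in this order:

* **catalyst** — one-hot over an ordered catalyst vocabulary (exactly one
  catalyst per condition record);
* **additives** — multi-hot; either class flags (acid / base / catalytic
  poison) or individual additive compounds, depending on the scheme;
* **temperature** — one-hot over ordered bins (°C), optionally all-zero with
  an "unknown" mask;
* **pressure** — one-hot over ordered bins (atm), same unknown convention.

Two stock schemes are provided. Scheme ``"S"`` (40 bits: 31 catalysts,
3 additive class flags, 3 temperature bins, 3 pressure bins) spans an
enumerable space of 2232 distinct conditions. Scheme ``"B"`` (365 bits: 227
catalysts, 131 additive compounds, 3 temperature bins, 4 pressure bins) spans
an astronomically large space (~7 × 10⁴²) that rules out exhaustive ranking —
the motivation for generative condition prediction.

Bins are half-open on the left: a boundary value belongs to the upper bin
(10 °C is "ambient", 1 atm is "ambient pressure").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConditionScheme",
    "ConditionVector",
    "ConditionRecord",
    "make_scheme",
    "bin_temperature",
    "bin_pressure",
    "encode",
    "decode",
    "space_size",
    "enumerate_space",
    "UNKNOWN",
]

#: sentinel for a missing temperature or pressure value
UNKNOWN = "unknown"

# dataset-S temperature bins: <10 °C cooling, 10–40 ambient, >40 heating
TEMP_EDGES = (10.0, 40.0)
TEMP_LABELS = ("cooling", "ambient temperature", "heating")
# dataset-B pressure bins: <1 atm low, 1–3.5 ambient, 3.5–100 elevated, >100 high
PRESSURE_EDGES_B = (1.0, 3.5, 100.0)
PRESSURE_LABELS_B = ("low pressure", "ambient pressure", "elevated pressure", "high pressure")
# dataset-S uses three pressure ranges (low / medium / high)
PRESSURE_EDGES_S = (3.5, 100.0)
PRESSURE_LABELS_S = ("low pressure", "medium pressure", "high pressure")

S_ADDITIVE_CLASSES = ("acid", "base", "catalytic poison")


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionScheme:
    """Bit layout for condition vectors: catalyst | additives | temp | pressure."""

    catalyst_vocab: tuple[str, ...]
    additive_vocab: tuple[str, ...]
    temp_bins: tuple[str, ...]
    temp_edges: tuple[float, ...]
    pressure_bins: tuple[str, ...]
    pressure_edges: tuple[float, ...]
    forbid_acid_base_together: bool = True
    allow_unknown_tp: bool = False
    name: str = "custom"

    def __post_init__(self):
        if not self.catalyst_vocab:
            raise SchemeError("catalyst vocabulary must not be empty")
        if len(self.temp_edges) != len(self.temp_bins) - 1:
            raise SchemeError("temperature edges must be one fewer than bins")
        if len(self.pressure_edges) != len(self.pressure_bins) - 1:
            raise SchemeError("pressure edges must be one fewer than bins")

    # block slices into the flat bit vector
    @property
    def n_bits(self) -> int:
        return (len(self.catalyst_vocab) + len(self.additive_vocab)
                + len(self.temp_bins) + len(self.pressure_bins))

    @property
    def catalyst_slice(self) -> slice:
        return slice(0, len(self.catalyst_vocab))

    @property
    def additive_slice(self) -> slice:
        a = len(self.catalyst_vocab)
        return slice(a, a + len(self.additive_vocab))

    @property
    def temp_slice(self) -> slice:
        a = len(self.catalyst_vocab) + len(self.additive_vocab)
        return slice(a, a + len(self.temp_bins))

    @property
    def pressure_slice(self) -> slice:
        a = len(self.catalyst_vocab) + len(self.additive_vocab) + len(self.temp_bins)
        return slice(a, a + len(self.pressure_bins))

    def block_slice(self, component: str) -> slice:
        try:
            return {"catalyst": self.catalyst_slice, "additives": self.additive_slice,
                    "temp": self.temp_slice, "pressure": self.pressure_slice}[component]
        except KeyError:
            raise SchemeError(f"unknown component {component!r}; expected catalyst|additives|temp|pressure")

    def _acid_base_indices(self) -> tuple[list[int], list[int]]:
        acids = [i for i, a in enumerate(self.additive_vocab) if a.startswith("acid")]
        bases = [i for i, a in enumerate(self.additive_vocab) if a.startswith("base")]
        return acids, bases


@dataclass(frozen=True)
class ConditionRecord:
    """Human-level condition assignment, the unit the generator and codec trade in."""

    catalyst: str
    additives: frozenset[str] = frozenset()
    temperature: float | str = UNKNOWN   # °C or UNKNOWN
    pressure: float | str = UNKNOWN      # atm or UNKNOWN


@dataclass(frozen=True)
class ConditionVector:
    """Concrete multi-hot assignment under a scheme.

    `bits` is a tuple of 0/1 ints of length ``scheme.n_bits``; `temp_unknown` /
    `pressure_unknown` flag all-zero ordinal blocks (only meaningful when the
    scheme allows unknown T/P).
    """

    bits: tuple[int, ...]
    scheme: ConditionScheme = field(compare=False)
    temp_unknown: bool = False
    pressure_unknown: bool = False

    def __post_init__(self):
        s = self.scheme
        if len(self.bits) != s.n_bits:
            raise SchemeError(f"expected {s.n_bits} bits, got {len(self.bits)}")
        b = np.asarray(self.bits)
        if b[s.catalyst_slice].sum() != 1:
            raise SchemeError("exactly one catalyst bit must be set")
        t_set = int(b[s.temp_slice].sum())
        p_set = int(b[s.pressure_slice].sum())
        if self.temp_unknown:
            if t_set != 0 or not s.allow_unknown_tp:
                raise SchemeError("unknown temperature requires an all-zero block and an allowing scheme")
        elif t_set != 1:
            raise SchemeError("exactly one temperature bit must be set")
        if self.pressure_unknown:
            if p_set != 0 or not s.allow_unknown_tp:
                raise SchemeError("unknown pressure requires an all-zero block and an allowing scheme")
        elif p_set != 1:
            raise SchemeError("exactly one pressure bit must be set")
        if s.forbid_acid_base_together:
            acids, bases = s._acid_base_indices()
            add = b[s.additive_slice]
            if acids and bases and add[acids].any() and add[bases].any():
                raise SchemeError("acid and base additives must not be set together")

    def block(self, component: str) -> tuple[int, ...]:
        return tuple(self.bits[self.scheme.block_slice(component)])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.float64)

    @property
    def tp_mask(self) -> tuple[bool, bool]:
        """(temperature known, pressure known)."""
        return (not self.temp_unknown, not self.pressure_unknown)

    def sort_key(self) -> tuple:
        """Canonical total order used for deterministic tie-breaking."""
        return (self.bits, self.temp_unknown, self.pressure_unknown)


# ----------------------------------------------------------------------
def make_scheme(kind: str = "S", *, catalyst_vocab=None, additive_vocab=None,
                temp_bins=None, temp_edges=None, pressure_bins=None,
                pressure_edges=None, allow_unknown_tp=None,
                forbid_acid_base_together=None) -> ConditionScheme:
    """Build a stock ``"S"``/``"B"`` scheme or a custom one.

    Scheme S: 31 catalysts + 3 additive class flags + 3 T bins + 3 P bins = 40 bits.
    Scheme B: 227 catalysts + 131 additive compounds + 3 T bins + 4 P bins = 365 bits,
    with unknown T/P allowed.
    """
    if kind == "S":
        return ConditionScheme(
            catalyst_vocab=tuple(catalyst_vocab) if catalyst_vocab is not None
            else tuple(_default_catalysts(31)),
            additive_vocab=S_ADDITIVE_CLASSES,
            temp_bins=TEMP_LABELS, temp_edges=TEMP_EDGES,
            pressure_bins=PRESSURE_LABELS_S, pressure_edges=PRESSURE_EDGES_S,
            forbid_acid_base_together=True, allow_unknown_tp=False, name="S")
    if kind == "B":
        return ConditionScheme(
            catalyst_vocab=tuple(catalyst_vocab) if catalyst_vocab is not None
            else tuple(_default_catalysts(227)),
            additive_vocab=tuple(additive_vocab) if additive_vocab is not None
            else tuple(f"additive_{i:03d}" for i in range(131)),
            temp_bins=TEMP_LABELS, temp_edges=TEMP_EDGES,
            pressure_bins=PRESSURE_LABELS_B, pressure_edges=PRESSURE_EDGES_B,
            forbid_acid_base_together=True, allow_unknown_tp=True, name="B")
    if kind != "custom":
        raise SchemeError(f"unknown scheme kind {kind!r}")
    return ConditionScheme(
        catalyst_vocab=tuple(catalyst_vocab),
        additive_vocab=tuple(additive_vocab or ()),
        temp_bins=tuple(temp_bins), temp_edges=tuple(temp_edges or ()),
        pressure_bins=tuple(pressure_bins), pressure_edges=tuple(pressure_edges or ()),
        forbid_acid_base_together=bool(True if forbid_acid_base_together is None
                                       else forbid_acid_base_together),
        allow_unknown_tp=bool(False if allow_unknown_tp is None else allow_unknown_tp))


_NAMED_CATALYSTS = (
    "Pd/C", "PtO2", "Raney Ni", "Rh/C", "Lindlar", "Pd(OH)2/C", "Ru/C", "Ni",
    "Pt/C", "Ir/C", "PdCl2", "RhCl(PPh3)3",
)


def _default_catalysts(n: int) -> list[str]:
    names = list(_NAMED_CATALYSTS[: min(n, len(_NAMED_CATALYSTS))])
    names += [f"catalyst_{i:03d}" for i in range(len(names), n)]
    return names


def _bin_value(value, edges, labels, allow_unknown: bool, what: str) -> int | str:
    if isinstance(value, str):
        if value == UNKNOWN:
            if not allow_unknown:
                raise SchemeError(f"{what} '{UNKNOWN}' not allowed by this scheme")
            return UNKNOWN
        raise SchemeError(f"{what} must be a number or '{UNKNOWN}', got {value!r}")
    v = float(value)
    if not np.isfinite(v):
        raise SchemeError(f"{what} must be finite")
    return int(np.searchsorted(edges, v, side="right"))


def bin_temperature(celsius, scheme: ConditionScheme):
    """Map °C to a bin index (or pass through :data:`UNKNOWN`). Half-open bins."""
    return _bin_value(celsius, scheme.temp_edges, scheme.temp_bins,
                      scheme.allow_unknown_tp, "temperature")


def bin_pressure(atm, scheme: ConditionScheme):
    """Map atm to a bin index (or pass through :data:`UNKNOWN`)."""
    return _bin_value(atm, scheme.pressure_edges, scheme.pressure_bins,
                      scheme.allow_unknown_tp, "pressure")


def encode(record: ConditionRecord, scheme: ConditionScheme) -> ConditionVector:
    """Encode a condition record into its multi-hot vector under `scheme`."""
    bits = np.zeros(scheme.n_bits, dtype=int)
    try:
        ci = scheme.catalyst_vocab.index(record.catalyst)
    except ValueError:
        raise SchemeError(
            f"catalyst {record.catalyst!r} not in vocabulary "
            f"({', '.join(scheme.catalyst_vocab[:5])}…)") from None
    bits[scheme.catalyst_slice.start + ci] = 1
    for a in record.additives:
        try:
            ai = scheme.additive_vocab.index(a)
        except ValueError:
            raise SchemeError(f"additive {a!r} not in vocabulary") from None
        bits[scheme.additive_slice.start + ai] = 1
    tb = bin_temperature(record.temperature, scheme)
    pb = bin_pressure(record.pressure, scheme)
    t_unknown = tb == UNKNOWN
    p_unknown = pb == UNKNOWN
    if not t_unknown:
        bits[scheme.temp_slice.start + tb] = 1
    if not p_unknown:
        bits[scheme.pressure_slice.start + pb] = 1
    return ConditionVector(tuple(int(x) for x in bits), scheme,
                           temp_unknown=t_unknown, pressure_unknown=p_unknown)


def decode(vector: ConditionVector) -> ConditionRecord:
    """Invert :func:`encode`; T/P come back as bin midpoint representatives.

    The numeric T/P values are the representative value of the assigned bin
    (its midpoint, or edge∓1 for the open end bins), chosen so that re-encoding
    reproduces the same bits.
    """
    s = vector.scheme
    b = np.asarray(vector.bits)
    catalyst = s.catalyst_vocab[int(np.argmax(b[s.catalyst_slice]))]
    additives = frozenset(a for i, a in enumerate(s.additive_vocab)
                          if b[s.additive_slice][i])
    temperature = (UNKNOWN if vector.temp_unknown
                   else _bin_representative(int(np.argmax(b[s.temp_slice])), s.temp_edges))
    pressure = (UNKNOWN if vector.pressure_unknown
                else _bin_representative(int(np.argmax(b[s.pressure_slice])), s.pressure_edges))
    return ConditionRecord(catalyst, additives, temperature, pressure)


def _bin_representative(idx: int, edges: tuple[float, ...]) -> float:
    if not edges:
        return 0.0
    if idx == 0:
        return edges[0] - 1.0
    if idx == len(edges):
        return edges[-1] + 1.0
    return 0.5 * (edges[idx - 1] + edges[idx])


def space_size(scheme: ConditionScheme) -> int:
    """Exact count of enumerable conditions: |T|·|P|·|catalysts|·2^|additives|.

    Unknown T/P are masks, not bins, and are not counted. Python integers keep
    the arithmetic exact even for the 2¹³¹-scale additive block of scheme B.
    """
    return (len(scheme.temp_bins) * len(scheme.pressure_bins)
            * len(scheme.catalyst_vocab) * 2 ** len(scheme.additive_vocab))


def enumerate_space(scheme: ConditionScheme, limit: int = 10_000_000):
    """Yield every valid ConditionVector (known T/P, any additive subset).

    Refuses schemes whose full space exceeds `limit`. Note: the acid/base
    exclusion applies to *records*, not the enumerable space — the space count
    follows the unrestricted 2^|additives| convention, so enumeration here
    does not apply the acid/base filter either.
    """
    n = space_size(scheme)
    if n > limit:
        raise SchemeError(f"condition space has {n} elements, above the {limit} cap")
    n_cat = len(scheme.catalyst_vocab)
    n_add = len(scheme.additive_vocab)
    for ci in range(n_cat):
        for add_bits in itertools.product((0, 1), repeat=n_add):
            for ti in range(len(scheme.temp_bins)):
                for pi in range(len(scheme.pressure_bins)):
                    bits = np.zeros(scheme.n_bits, dtype=int)
                    bits[scheme.catalyst_slice.start + ci] = 1
                    bits[scheme.additive_slice] = add_bits
                    bits[scheme.temp_slice.start + ti] = 1
                    bits[scheme.pressure_slice.start + pi] = 1
                    yield tuple(int(x) for x in bits)


def vector_from_bits(bits, scheme: ConditionScheme,
                     temp_unknown: bool = False,
                     pressure_unknown: bool = False) -> ConditionVector:
    return ConditionVector(tuple(int(x) for x in bits), scheme,
                           temp_unknown=temp_unknown, pressure_unknown=pressure_unknown)
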