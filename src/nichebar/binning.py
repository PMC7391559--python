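"""Binned-range (BR) coding of ecological niches.

One environmental axis (e.g. mean annual temperature) is discretized into
equal-width bins spanning the union of all accessible areas (M) of the
species in a clade.  Each species' niche is then written as a vector over
the three-symbol alphabet

* ``"1"`` — suitable: the bin intersects the range of conditions the
  species is observed to occupy;
* ``"0"`` — unsuitable: the bin's conditions exist inside the species' M
  but the species does not occupy them;
* ``"?"`` — unknown: nothing in the species' M tells us whether the bin is
  suitable (typically because the occupied limit coincides with the limit
  of environments available in M — a *truncated* niche estimate).

Coding ``?`` explicitly is the point: downstream ancestral reconstruction
can then distinguish "known unsuitable" from "never observable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SUITABLE = "1"
UNSUITABLE = "0"
UNKNOWN = "?"
SYMBOLS = (UNSUITABLE, SUITABLE, UNKNOWN)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class EnvRange:
    """A closed interval of environmental values, ``min <= max``."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.min) and math.isfinite(self.max)):
            raise ValueError("EnvRange bounds must be finite")
        if self.min > self.max:
            raise ValueError(f"EnvRange min {self.min} > max {self.max}")

    @property
    def extent(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class BinScheme:
    """An ordered partition of ``[lower_edge, upper_edge]`` into equal-width bins.

    Bins are half-open ``[edges[i], edges[i+1])`` except the last, which is
    closed so that the scheme tiles the interval exactly.
    """

    axis_name: str
    width: float
    lower_edge: float
    upper_edge: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        n = (self.upper_edge - self.lower_edge) / self.width
        if abs(n - round(n)) > _REL_TOL * max(1.0, abs(n)) or round(n) < 1:
            raise ValueError(
                "scheme extent must be a positive integer multiple of width"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.upper_edge - self.lower_edge) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.lower_edge + self.width * np.arange(self.n_bins + 1)

    def bin_index(self, value: float) -> int:
        """Index of the bin containing ``value`` (last bin closed above)."""
        tol = _REL_TOL * max(1.0, abs(self.lower_edge), abs(self.upper_edge))
        if value < self.lower_edge - tol or value > self.upper_edge + tol:
            raise ValueError(
                f"value {value} outside scheme [{self.lower_edge}, {self.upper_edge}]"
            )
        if value >= self.upper_edge:
            return self.n_bins - 1
        i = min(int((value - self.lower_edge) // self.width), self.n_bins - 1)
        # float division can land one bin off near an edge; fix against edges
        e = self.edges
        if i + 1 < self.n_bins and value >= e[i + 1]:
            i += 1
        elif i > 0 and value < e[i]:
            i -= 1
        return i

    def labels(self) -> list[str]:
        """Per-bin ``lower_upper`` labels, e.g. ``"3_4"``."""
        e = self.edges
        return [f"{e[i]:g}_{e[i + 1]:g}" for i in range(self.n_bins)]


def _as_values(x) -> np.ndarray | None:
    if isinstance(x, EnvRange):
        return None
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty value set")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite environmental values")
    return arr


@dataclass(frozen=True)
class SpeciesEnvProfile:
    """One species' environmental evidence.

    ``occupied`` holds the realized-niche side (conditions at occupied
    cells/occurrences), ``accessible`` the conditions present anywhere in
    the species' accessible area M.  Both are either :class:`EnvRange`
    summaries (``mode == "range"``) or explicit value arrays sampled from
    grid cells (``mode == "values"``).
    """

    species_id: str
    occupied: EnvRange | np.ndarray
    accessible: EnvRange | np.ndarray

    def __post_init__(self) -> None:
        occ_vals = _as_values(self.occupied)
        acc_vals = _as_values(self.accessible)
        if (occ_vals is None) != (acc_vals is None):
            raise ValueError("occupied and accessible must share a mode")
        if occ_vals is None:
            if (
                self.occupied.min < self.accessible.min - _REL_TOL
                or self.occupied.max > self.accessible.max + _REL_TOL
            ):
                raise ValueError(
                    f"{self.species_id}: occupied range not contained in accessible range"
                )
        else:
            object.__setattr__(self, "occupied", occ_vals)
            object.__setattr__(self, "accessible", acc_vals)
            if occ_vals.min() < acc_vals.min() or occ_vals.max() > acc_vals.max():
                raise ValueError(
                    f"{self.species_id}: occupied values outside accessible values"
                )

    @property
    def mode(self) -> str:
        return "range" if isinstance(self.occupied, EnvRange) else "values"

    def occupied_range(self, trim: tuple[float, float] | None = None) -> EnvRange:
        """Occupied min/max; optional symmetric percentile trim in values mode."""
        if self.mode == "range":
            return self.occupied
        vals = self.occupied
        if trim is not None:
            lo, hi = trim
            return EnvRange(float(np.percentile(vals, lo)), float(np.percentile(vals, hi)))
        return EnvRange(float(vals.min()), float(vals.max()))

    def accessible_range(self) -> EnvRange:
        if self.mode == "range":
            return self.accessible
        return EnvRange(float(self.accessible.min()), float(self.accessible.max()))


@dataclass(frozen=True)
class CharacterVector:
    """A species' (or node's) niche as bin states over ``{0, 1, ?}``."""

    species_id: str
    scheme: BinScheme
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) != self.scheme.n_bins:
            raise ValueError("state vector length != number of bins")
        bad = set(self.states) - set(SYMBOLS)
        if bad:
            raise ValueError(f"invalid state symbols: {sorted(bad)}")

    def suitable_span(self) -> tuple[int, int] | None:
        """(first, last) indices of suitable bins, or None if none."""
        idx = [i for i, s in enumerate(self.states) if s == SUITABLE]
        if not idx:
            return None
        return idx[0], idx[-1]


@dataclass
class CharacterMatrix:
    """Species x bins character table sharing one :class:`BinScheme`."""

    scheme: BinScheme
    rows: list[CharacterVector] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.species_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in character matrix")
        for r in self.rows:
            if r.scheme != self.scheme:
                raise ValueError(f"{r.species_id}: row scheme differs from matrix scheme")

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.rows]

    def __getitem__(self, species_id: str) -> CharacterVector:
        for r in self.rows:
            if r.species_id == species_id:
                return r
        raise KeyError(species_id)

    def __len__(self) -> int:
        return len(self.rows)


def union_env_range(profiles: Sequence[SpeciesEnvProfile]) -> EnvRange:
    """Min/max environmental value over the union of all accessible areas."""
    if not profiles:
        raise ValueError("no profiles")
    ranges = [p.accessible_range() for p in profiles]
    return EnvRange(min(r.min for r in ranges), max(r.max for r in ranges))


def build_bin_scheme(
    global_range: EnvRange, width: float, axis_name: str = "env"
) -> BinScheme:
    """Equal-width bins covering ``global_range``, edges aligned outward to
    multiples of ``width`` (so a 3–35 range at width 1 gives integer-degree
    bins 3_4 ... 34_35)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    if global_range.extent <= 0:
        raise ValueError("degenerate range")
    # snap to the grid when min/width is within rounding noise of an integer
    lo_q = global_range.min / width
    hi_q = global_range.max / width
    lo = math.floor(lo_q + _REL_TOL * max(1.0, abs(lo_q))) * width
    hi = math.ceil(hi_q - _REL_TOL * max(1.0, abs(hi_q))) * width
    return BinScheme(axis_name=axis_name, width=width, lower_edge=lo, upper_edge=hi)


def _bin_has_value(scheme: BinScheme, i: int, values: np.ndarray) -> bool:
    lo, hi = scheme.edges[i], scheme.edges[i + 1]
    if i == scheme.n_bins - 1:
        return bool(np.any((values >= lo) & (values <= hi)))
    return bool(np.any((values >= lo) & (values < hi)))


def _bin_intersects(scheme: BinScheme, i: int, r: EnvRange) -> bool:
    lo, hi = scheme.edges[i], scheme.edges[i + 1]
    if i == scheme.n_bins - 1:
        return lo <= r.max and hi >= r.min
    return lo <= r.max and hi > r.min


def code_species_bins(
    profile: SpeciesEnvProfile,
    scheme: BinScheme,
    *,
    eps: float | None = None,
    trim: tuple[float, float] | None = None,
    fill_gaps: bool = False,
) -> CharacterVector:
    """Code one species' niche over a bin scheme.

    A bin is suitable when it intersects the occupied range (range mode) or
    contains at least one occupied value (values mode).  A niche limit is
    *truncated* when the occupied extreme lies within ``eps`` of (or beyond)
    the accessible extreme on that side; bins beyond the suitable run on a
    truncated side are unknown, on a characterized side unsuitable.  In
    values mode a bin with no accessible value carries no M evidence and is
    unknown.  ``fill_gaps`` additionally converts interior unsuitable bins
    (possible only in values mode with patchy M environments) to suitable
    under the unimodal-response assumption.
    """
    if eps is None:
        eps = 1e-6 * scheme.width
    occ = profile.occupied_range(trim=trim)
    acc = profile.accessible_range()
    if occ.min < scheme.lower_edge - _REL_TOL or occ.max > scheme.upper_edge + _REL_TOL:
        raise ValueError(f"{profile.species_id}: profile exceeds scheme")

    values_mode = profile.mode == "values"
    if values_mode:
        occ_vals = profile.occupied
        if trim is not None:
            occ_vals = occ_vals[(occ_vals >= occ.min) & (occ_vals <= occ.max)]
        suitable = np.array(
            [_bin_has_value(scheme, i, occ_vals) for i in range(scheme.n_bins)]
        )
    else:
        suitable = np.array(
            [_bin_intersects(scheme, i, occ) for i in range(scheme.n_bins)]
        )
    if not suitable.any():
        raise ValueError(f"{profile.species_id}: no suitable bin")

    truncated_low = occ.min <= acc.min + eps
    truncated_high = occ.max >= acc.max - eps
    first = int(np.argmax(suitable))
    last = int(scheme.n_bins - 1 - np.argmax(suitable[::-1]))

    states = []
    for i in range(scheme.n_bins):
        if suitable[i]:
            states.append(SUITABLE)
        elif i < first:
            if truncated_low:
                states.append(UNKNOWN)
            elif values_mode and not _bin_has_value(scheme, i, profile.accessible):
                states.append(UNKNOWN)
            else:
                states.append(UNSUITABLE)
        elif i > last:
            if truncated_high:
                states.append(UNKNOWN)
            elif values_mode and not _bin_has_value(scheme, i, profile.accessible):
                states.append(UNKNOWN)
            else:
                states.append(UNSUITABLE)
        else:  # interior gap, values mode only
            if fill_gaps:
                states.append(SUITABLE)
            elif values_mode and not _bin_has_value(scheme, i, profile.accessible):
                states.append(UNKNOWN)
            else:
                states.append(UNSUITABLE)

    vec = CharacterVector(profile.species_id, scheme, tuple(states))
    return fill_flanked_unknowns(vec)


def fill_flanked_unknowns(vector: CharacterVector) -> CharacterVector:
    """Convert every maximal run of ``?`` flanked by suitable bins to ``1``.

    Idempotent; never touches ``1`` or ``0`` bins.  Implements the unimodal
    response assumption at the tip level.
    """
    states = list(vector.states)
    n = len(states)
    i = 0
    while i < n:
        if states[i] == UNKNOWN:
            j = i
            while j < n and states[j] == UNKNOWN:
                j += 1
            if i > 0 and j < n and states[i - 1] == SUITABLE and states[j] == SUITABLE:
                for k in range(i, j):
                    states[k] = SUITABLE
            i = j
        else:
            i += 1
    return CharacterVector(vector.species_id, vector.scheme, tuple(states))


def code_matrix(
    profiles: Iterable[SpeciesEnvProfile],
    scheme: BinScheme | None = None,
    *,
    width: float | None = None,
    axis_name: str = "env",
    **coding_kwargs,
) -> CharacterMatrix:
    """Code a set of species against one scheme.

    If ``scheme`` is omitted it is built from the union of the profiles'
    accessible ranges at the given ``width``.
    """
    profiles = list(profiles)
    if scheme is None:
        if width is None:
            raise ValueError("either scheme or width is required")
        scheme = build_bin_scheme(union_env_range(profiles), width, axis_name=axis_name)
    rows = [code_species_bins(p, scheme, **coding_kwargs) for p in profiles]
    return CharacterMatrix(scheme=scheme, rows=rows)
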