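"""Allele profiles, species presence calls, and popANI/conANI comparison.

The atomic input is an :class:`AlleleProfile`: for one sample and one species
(reference genome), the read counts of A, C, G and T at every covered genome
position. Two samples are compared only at positions covered at or above a
depth threshold in *both* samples. Two substitution definitions are computed
side by side:

* **conANI** (consensus ANI) counts a substitution wherever the two samples'
  consensus (majority) alleles differ.
* **popANI** (population ANI) is microdiversity-aware: a position counts as a
  substitution only when the two samples share *no* detected allele there,
  major or minor. Shared minor alleles therefore suppress popANI
  substitutions, so popANI >= conANI always.

Two samples carry the same strain of a species when the species passes the
joint presence criterion (breadth of the genome covered at >= ``min_depth``
in both samples) and popANI meets the strain-identity threshold
(default 99.999%).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

BASES = ("A", "C", "G", "T")

#: default depth for a position to be comparable / countable toward breadth
DEFAULT_MIN_DEPTH = 5
#: default fraction of the genome that must be covered for a species to be
#: called present in a sample
DEFAULT_MIN_BREADTH = 0.25
#: allele detection: minimum read count and minimum within-site frequency
DEFAULT_MIN_COUNT = 2
DEFAULT_MIN_FREQ = 0.05
#: popANI at or above this value means "same strain"
DEFAULT_ANI_THRESHOLD = 0.99999


@dataclasses.dataclass(frozen=True)
class AlleleProfile:
    """Per-sample, per-species sparse base counts.

    Parameters
    ----------
    sample_id, species_id
        Identifiers.
    genome_length
        Total length (bp) of the species' reference genome. Scaffolds are
        concatenated by the reader, so ``positions`` are 0-based per-genome
        coordinates.
    positions
        Sorted, unique int array of covered positions, all < genome_length.
    counts
        ``(len(positions), 4)`` non-negative int array of A, C, G, T counts.
    """

    sample_id: str
    species_id: str
    genome_length: int
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "counts", counts)
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if counts.shape != (positions.size, 4):
            raise ValueError(
                f"counts must have shape (n_positions, 4); got {counts.shape}"
            )
        if positions.size:
            if positions[0] < 0 or positions[-1] >= self.genome_length:
                raise ValueError("positions must lie in [0, genome_length)")
            if np.any(np.diff(positions) <= 0):
                raise ValueError("positions must be sorted and unique")
        if np.any(counts < 0):
            raise ValueError("base counts must be non-negative")

    @property
    def depths(self) -> np.ndarray:
        """Read depth (sum of the four base counts) at each covered position."""
        return self.counts.sum(axis=1)

    def __repr__(self) -> str:  # keep numpy arrays out of reprs
        return (
            f"AlleleProfile(sample_id={self.sample_id!r}, "
            f"species_id={self.species_id!r}, genome_length={self.genome_length}, "
            f"n_sites={self.positions.size})"
        )


@dataclasses.dataclass(frozen=True)
class PresenceCall:
    sample_id: str
    species_id: str
    breadth: float
    mean_depth: float
    present: bool


@dataclasses.dataclass(frozen=True)
class PairwiseComparison:
    """popANI/conANI comparison of one species between two samples.

    ``n_compared`` is the number of positions covered at >= min_depth in both
    samples. When ``n_compared`` is zero the comparison is non-evaluable and
    the ANI fields are None.
    """

    sample_a: str
    sample_b: str
    species_id: str
    n_compared: int
    n_pop_subs: int
    n_con_subs: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_pop_subs <= self.n_con_subs <= self.n_compared:
            raise ValueError(
                "require 0 <= n_pop_subs <= n_con_subs <= n_compared; got "
                f"{self.n_pop_subs}, {self.n_con_subs}, {self.n_compared}"
            )

    @property
    def evaluable(self) -> bool:
        return self.n_compared > 0

    @property
    def popani(self) -> float | None:
        if not self.evaluable:
            return None
        return 1.0 - self.n_pop_subs / self.n_compared

    @property
    def conani(self) -> float | None:
        if not self.evaluable:
            return None
        return 1.0 - self.n_con_subs / self.n_compared


def detect_alleles(
    site_counts: Iterable[int],
    min_count: int = DEFAULT_MIN_COUNT,
    min_freq: float = DEFAULT_MIN_FREQ,
) -> set[str]:
    """Detected alleles at one site: bases with count >= ``min_count`` and
    frequency >= ``min_freq``. A zero-depth site yields the empty set (the
    site is not comparable)."""
    c = np.asarray(list(site_counts), dtype=np.int64)
    if c.shape != (4,):
        raise ValueError("site_counts must supply exactly four base counts")
    if np.any(c < 0):
        raise ValueError("base counts must be non-negative")
    depth = int(c.sum())
    if depth == 0:
        return set()
    mask = (c >= min_count) & (c / depth >= min_freq)
    return {BASES[i] for i in np.flatnonzero(mask)}


def _allele_masks(counts: np.ndarray, min_count: int, min_freq: float) -> np.ndarray:
    """Vectorised detect_alleles: boolean (n_sites, 4) detection mask."""
    depths = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(depths > 0, counts / np.maximum(depths, 1), 0.0)
    return (counts >= min_count) & (freqs >= min_freq)


def presence_call(
    profile: AlleleProfile,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_breadth: float = DEFAULT_MIN_BREADTH,
) -> PresenceCall:
    """Call a species present when >= ``min_breadth`` of its genome is covered
    at >= ``min_depth``. ``mean_depth`` is averaged over the whole genome."""
    depths = profile.depths
    covered = int(np.count_nonzero(depths >= min_depth))
    breadth = covered / profile.genome_length
    mean_depth = float(depths.sum()) / profile.genome_length
    return PresenceCall(
        sample_id=profile.sample_id,
        species_id=profile.species_id,
        breadth=breadth,
        mean_depth=mean_depth,
        present=breadth >= min_breadth,
    )


def compare_profiles(
    a: AlleleProfile,
    b: AlleleProfile,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_count: int = DEFAULT_MIN_COUNT,
    min_freq: float = DEFAULT_MIN_FREQ,
) -> PairwiseComparison:
    """Compare two allele profiles of the same species.

    Positions covered at >= ``min_depth`` in both samples are compared. A
    popANI substitution is a position whose detected-allele sets are
    disjoint; a conANI substitution is a position whose consensus alleles
    differ (argmax over counts, ties broken lexicographically A<C<G<T).
    """
    if a.species_id != b.species_id:
        raise ValueError(
            f"species mismatch: {a.species_id!r} vs {b.species_id!r}"
        )
    if a.genome_length != b.genome_length:
        raise ValueError("profiles disagree on genome_length")

    _, ia, ib = np.intersect1d(
        a.positions, b.positions, assume_unique=True, return_indices=True
    )
    ca = a.counts[ia]
    cb = b.counts[ib]
    keep = (ca.sum(axis=1) >= min_depth) & (cb.sum(axis=1) >= min_depth)
    ca = ca[keep]
    cb = cb[keep]
    n_compared = int(ca.shape[0])
    if n_compared == 0:
        return PairwiseComparison(
            a.sample_id, b.sample_id, a.species_id, 0, 0, 0
        )

    ma = _allele_masks(ca, min_count, min_freq)
    mb = _allele_masks(cb, min_count, min_freq)
    pop_sub = ~np.any(ma & mb, axis=1)
    # np.argmax returns the first maximum, i.e. the lexicographically
    # smallest base among ties given the fixed A,C,G,T column order.
    con_sub = np.argmax(ca, axis=1) != np.argmax(cb, axis=1)
    # Disjoint detected-allele sets imply differing consensus alleles for any
    # thresholds where the consensus is detected; enforce the containment so
    # the popANI >= conANI invariant survives exotic threshold choices too.
    con_sub |= pop_sub
    return PairwiseComparison(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        species_id=a.species_id,
        n_compared=n_compared,
        n_pop_subs=int(pop_sub.sum()),
        n_con_subs=int(con_sub.sum()),
    )


def is_strain_shared(
    comparison: PairwiseComparison,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
) -> bool:
    """True when popANI >= ``ani_threshold``.

    Only meaningful when the species passed the joint presence criterion;
    raises on a non-evaluable comparison (zero compared positions).
    """
    if not comparison.evaluable:
        raise ValueError(
            "comparison is non-evaluable (no jointly covered positions); "
            f"{comparison.sample_a} vs {comparison.sample_b} "
            f"[{comparison.species_id}]"
        )
    return comparison.popani >= ani_threshold
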