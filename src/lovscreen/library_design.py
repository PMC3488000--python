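"""Degenerate-codon library design and screening-coverage statistics.

Site-saturation mutagenesis replaces one codon with a degenerate triplet
(typically NNK: N = any base, K = G or T) so that every amino acid is
sampled at the target position.  This module enumerates such libraries,
computes the amino-acid distribution they encode, answers the screening
question "how many clones must I pick to see every variant?", and builds
and validates the degenerate mutagenic primers that implement the scheme.

Coverage here means *complete* coverage: the probability that every
variant of the library appears at least once among ``n`` independently
sampled clones (the coupon-collector event).  The expected *fraction* of
variants seen, which is the quantity behind the common
``n = -V ln(1 - F)`` oversampling rule, is exposed separately as
:func:`expected_coverage_fraction`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_DNA",
    "DegenerateCodon",
    "DegenerateLibrary",
    "CoverageResult",
    "MutagenicPrimer",
    "InvalidCodonError",
    "PrimerFormatError",
    "CoverageError",
    "expand_degenerate_codon",
    "amino_acid_distribution",
    "coverage_probability",
    "expected_coverage_fraction",
    "required_clones",
    "oversampling_factor",
    "build_mutagenic_primer",
    "validate_primer",
    "read_library_specs",
    "write_primers_fasta",
]

#: IUPAC nucleotide ambiguity codes and the concrete bases they stand for.
IUPAC_DNA: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_DEGENERATE = frozenset(IUPAC_DNA) - frozenset("ACGT")

#: Symbol used for translation-stop "residues" in amino-acid distributions.
STOP = "*"

#: Default seed of the Monte-Carlo coverage fallback.
DEFAULT_MC_SEED = 20121024

#: Default replicate count of the Monte-Carlo coverage fallback.
DEFAULT_MC_REPLICATES = 100_000

#: Largest variant count for which the general (unequal-probability)
#: subset inclusion-exclusion sum is evaluated; 2**20 terms.
MAX_EXACT_SUBSET_VARIANTS = 20


class InvalidCodonError(ValueError):
    """A triplet contains a character that is not an IUPAC nucleotide code."""


class PrimerFormatError(ValueError):
    """A primer sequence violates the single-degenerate-codon layout."""


class CoverageError(ValueError):
    """Coverage statistics were requested for an ill-posed library."""


@dataclass(frozen=True)
class DegenerateCodon:
    """A three-letter degenerate codon in IUPAC nucleotide code."""

    triplet: str

    def __post_init__(self) -> None:
        if len(self.triplet) != 3:
            raise InvalidCodonError(
                f"codon must have exactly 3 characters, got {self.triplet!r}"
            )
        for pos, char in enumerate(self.triplet):
            if char not in IUPAC_DNA:
                raise InvalidCodonError(
                    f"invalid IUPAC nucleotide code {char!r} at position {pos} "
                    f"of {self.triplet!r}"
                )

    @property
    def degeneracy(self) -> int:
        """Number of concrete codons the triplet expands to."""
        return math.prod(len(IUPAC_DNA[c]) for c in self.triplet)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.triplet


def _as_codon(codon: DegenerateCodon | str) -> DegenerateCodon:
    return codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)


def expand_degenerate_codon(codon: DegenerateCodon | str) -> tuple[str, ...]:
    """Expand a degenerate codon into its concrete triplets.

    Returns the Cartesian product of the per-position IUPAC expansions,
    sorted lexicographically so serialisation is deterministic.

    >>> len(expand_degenerate_codon("NNK"))
    32
    """
    codon = _as_codon(codon)
    per_position = [IUPAC_DNA[c] for c in codon.triplet]
    return tuple(sorted("".join(bases) for bases in itertools.product(*per_position)))


def amino_acid_distribution(
    codon: DegenerateCodon | str, include_stop: bool = True
) -> dict[str, float]:
    """Amino-acid probabilities encoded by a degenerate codon.

    Each concrete codon of the expansion is equally likely; the
    probability of residue ``r`` is the fraction of expanded codons that
    translate to ``r`` under the standard genetic code.  Stop codons are
    reported under ``"*"`` when ``include_stop`` is true, otherwise they
    are dropped and the remaining probabilities renormalised.
    """
    expansion = expand_degenerate_codon(codon)
    counts: dict[str, int] = {}
    for triplet in expansion:
        residue = standard_dna_table.forward_table.get(triplet, STOP)
        counts[residue] = counts.get(residue, 0) + 1
    if not include_stop:
        counts.pop(STOP, None)
        if not counts:
            raise CoverageError(
                f"codon {codon!s} encodes only stop codons; nothing to renormalise"
            )
    total = sum(counts.values())
    return {residue: count / total for residue, count in sorted(counts.items())}


@dataclass
class DegenerateLibrary:
    """A single-site saturation library and its variant distribution.

    ``level`` selects whether variants are counted as concrete codons
    (the arithmetic behind "32 possible mutations" for NNK) or as amino
    acids (20 residues plus, optionally, the stop).
    """

    scheme: DegenerateCodon
    level: Literal["codon", "amino_acid"] = "codon"
    include_stop: bool = True
    codons: tuple[str, ...] = field(init=False)
    variant_probs: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.scheme = _as_codon(self.scheme)
        self.codons = expand_degenerate_codon(self.scheme)
        if self.level == "codon":
            n = len(self.codons)
            self.variant_probs = {c: 1.0 / n for c in self.codons}
        elif self.level == "amino_acid":
            self.variant_probs = amino_acid_distribution(
                self.scheme, include_stop=self.include_stop
            )
        else:
            raise ValueError(f"unknown library level {self.level!r}")

    def __len__(self) -> int:
        return len(self.variant_probs)


@dataclass(frozen=True)
class CoverageResult:
    """Probability that ``n_clones`` draws cover every library variant."""

    n_clones: int
    p_complete: float
    confidence_target: float | None
    method: Literal["exact", "monte_carlo"]
    mc_se: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_complete <= 1.0:
            raise ValueError("p_complete must lie in [0, 1]")
        if self.method == "exact" and self.mc_se != 0.0:
            raise ValueError("exact coverage carries no Monte-Carlo error")


def _check_probs(variant_probs: Sequence[float] | np.ndarray) -> np.ndarray:
    probs = np.asarray(variant_probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise CoverageError("variant probabilities must be a non-empty 1-d vector")
    if np.any(probs < 0):
        raise CoverageError("variant probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise CoverageError(f"variant probabilities sum to {probs.sum()}, not 1")
    return probs


def _probs_of(library: "DegenerateLibrary | Sequence[float]") -> np.ndarray:
    if isinstance(library, DegenerateLibrary):
        return _check_probs(list(library.variant_probs.values()))
    return _check_probs(library)


def _coverage_exact_uniform(n: int, m: int) -> float:
    # Inclusion-exclusion collapses to m+1 binomial terms when every
    # variant is equally likely: sum_k (-1)^k C(m,k) (1-k/m)^n.
    terms = [
        (-1.0) ** k * math.comb(m, k) * ((m - k) / m) ** n for k in range(m + 1)
    ]
    return min(1.0, max(0.0, math.fsum(terms)))


def _coverage_exact_general(n: int, probs: np.ndarray) -> float:
    # Full subset inclusion-exclusion; 2^m terms built by doubling.
    subset_sums = np.zeros(1)
    signs = np.ones(1)
    for p in probs:
        subset_sums = np.concatenate([subset_sums, subset_sums + p])
        signs = np.concatenate([signs, -signs])
    missing = np.clip(1.0 - subset_sums, 0.0, 1.0)
    return float(min(1.0, max(0.0, np.sum(signs * missing**n))))


def _coverage_monte_carlo(
    n: int, probs: np.ndarray, replicates: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    m = probs.size
    covered = 0
    chunk = max(1, min(replicates, 4_000_000 // max(n, 1)))
    done = 0
    while done < replicates:
        size = min(chunk, replicates - done)
        draws = rng.choice(m, size=(size, n), p=probs)
        seen = np.zeros((size, m), dtype=bool)
        seen[np.arange(size)[:, None], draws] = True
        covered += int(seen.all(axis=1).sum())
        done += size
    p_hat = covered / replicates
    se = math.sqrt(p_hat * (1.0 - p_hat) / replicates)
    return p_hat, se


def coverage_probability(
    n_clones: int,
    library: DegenerateLibrary | Sequence[float],
    *,
    method: Literal["auto", "exact", "monte_carlo"] = "auto",
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = DEFAULT_MC_SEED,
) -> CoverageResult:
    """Probability that every variant appears among ``n_clones`` i.i.d. draws.

    The exact inclusion-exclusion answer is used whenever it is cheap:
    the equal-probability case collapses to ``m + 1`` terms for any
    library size, and unequal probabilities are enumerated over variant
    subsets up to :data:`MAX_EXACT_SUBSET_VARIANTS` variants.  Larger
    unequal-probability libraries fall back to a seeded Monte-Carlo
    estimate whose standard error is reported in ``mc_se``.
    """
    if n_clones < 0:
        raise CoverageError("n_clones must be non-negative")
    probs = _probs_of(library)
    m = probs.size

    uniform = bool(np.allclose(probs, probs[0], rtol=0.0, atol=1e-12))
    if method == "auto":
        if uniform or m <= MAX_EXACT_SUBSET_VARIANTS:
            method = "exact"
        else:
            method = "monte_carlo"

    if method == "exact":
        if uniform:
            p = _coverage_exact_uniform(n_clones, m)
        elif m <= MAX_EXACT_SUBSET_VARIANTS:
            p = _coverage_exact_general(n_clones, probs)
        else:
            raise CoverageError(
                f"exact coverage is limited to {MAX_EXACT_SUBSET_VARIANTS} "
                f"unequal-probability variants (got {m}); use monte_carlo"
            )
        return CoverageResult(n_clones, p, None, "exact")

    p_hat, se = _coverage_monte_carlo(n_clones, probs, mc_replicates, seed)
    return CoverageResult(n_clones, p_hat, None, "monte_carlo", mc_se=se)


def expected_coverage_fraction(
    n_clones: int, library: DegenerateLibrary | Sequence[float]
) -> float:
    """Expected fraction of variants seen at least once among ``n_clones``.

    For a uniform library of ``V`` variants this is
    ``1 - (1 - 1/V)**n``, the quantity behind the familiar
    ``n = -V ln(1 - F)`` screening rule of thumb (96 NNK clones give
    F = 0.95); it is far less demanding than complete coverage.
    """
    if n_clones < 0:
        raise CoverageError("n_clones must be non-negative")
    probs = _probs_of(library)
    return float(np.mean(1.0 - (1.0 - probs) ** n_clones))


def required_clones(
    library: DegenerateLibrary | Sequence[float],
    confidence: float,
    **coverage_kwargs,
) -> int:
    """Smallest clone count whose complete-coverage probability meets ``confidence``.

    Found by doubling until the (monotone) coverage curve crosses the
    target, then bisecting; the smallest qualifying ``n`` is returned.
    """
    if not 0.0 < confidence < 1.0:
        raise CoverageError("confidence must lie strictly between 0 and 1")
    probs = _probs_of(library)
    if np.any(probs <= 0.0):
        raise CoverageError(
            "a variant with zero probability can never be covered"
        )

    def cov(n: int) -> float:
        return coverage_probability(n, probs, **coverage_kwargs).p_complete

    hi = 1
    while cov(hi) < confidence:
        hi *= 2
        if hi > 2**40:  # pragma: no cover - defensive
            raise CoverageError("coverage target not reachable at any feasible n")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if cov(mid) >= confidence:
            hi = mid
        else:
            lo = mid
    return hi if cov(hi) >= confidence else hi + 1


def oversampling_factor(
    n_clones: int, library: DegenerateLibrary | DegenerateCodon | str
) -> float:
    """Ratio of clones screened to library variants (e.g. 180/32 = 5.625)."""
    if not isinstance(library, DegenerateLibrary):
        library = DegenerateLibrary(_as_codon(library))
    size = len(library)
    if size == 0:
        raise CoverageError("library has no variants")
    return n_clones / size


# ---------------------------------------------------------------------------
# Mutagenic primers


@dataclass(frozen=True)
class MutagenicPrimer:
    """A mutagenic oligo: concrete flanks around one degenerate codon."""

    sequence: str
    degenerate_start: int
    upstream_flank: str
    scheme: DegenerateCodon
    downstream_flank: str

    def __post_init__(self) -> None:
        expected = self.upstream_flank + self.scheme.triplet + self.downstream_flank
        if self.sequence != expected:
            raise PrimerFormatError("primer sequence does not match its parts")


def _check_concrete_flank(flank: str, label: str, min_length: int) -> None:
    if len(flank) < min_length:
        raise PrimerFormatError(
            f"{label} flank has {len(flank)} nt; at least {min_length} required"
        )
    bad = set(flank) - set("ACGT")
    if bad:
        raise PrimerFormatError(
            f"{label} flank contains degenerate or invalid characters: {sorted(bad)}"
        )


def build_mutagenic_primer(
    upstream_flank: str,
    scheme: DegenerateCodon | str,
    downstream_flank: str,
    *,
    min_flank_length: int = 10,
) -> MutagenicPrimer:
    """Assemble a saturation-mutagenesis primer around a degenerate codon.

    Degeneracy is allowed only in the target triplet; both flanks must
    be concrete DNA of at least ``min_flank_length`` nucleotides so the
    oligo anneals specifically on either side of the mutated codon.
    """
    scheme = _as_codon(scheme)
    _check_concrete_flank(upstream_flank, "upstream", min_flank_length)
    _check_concrete_flank(downstream_flank, "downstream", min_flank_length)
    sequence = upstream_flank + scheme.triplet + downstream_flank
    return MutagenicPrimer(
        sequence=sequence,
        degenerate_start=len(upstream_flank),
        upstream_flank=upstream_flank,
        scheme=scheme,
        downstream_flank=downstream_flank,
    )


def validate_primer(primer_sequence: str) -> tuple[int, DegenerateCodon]:
    """Locate the unique 3-nt degenerate block of a mutagenic primer.

    Returns the 0-based offset and the degenerate codon.  Fails if the
    sequence contains no degenerate characters, more than one degenerate
    run, or a run whose length is not exactly 3.
    """
    if not primer_sequence:
        raise PrimerFormatError("empty primer sequence")
    for pos, char in enumerate(primer_sequence):
        if char not in IUPAC_DNA:
            raise InvalidCodonError(
                f"invalid IUPAC nucleotide code {char!r} at position {pos}"
            )
    runs: list[tuple[int, int]] = []  # (start, length)
    i = 0
    while i < len(primer_sequence):
        if primer_sequence[i] in _DEGENERATE:
            start = i
            while i < len(primer_sequence) and primer_sequence[i] in _DEGENERATE:
                i += 1
            runs.append((start, i - start))
        else:
            i += 1
    if not runs:
        raise PrimerFormatError("no degenerate block found")
    if len(runs) > 1:
        raise PrimerFormatError(f"multiple degenerate blocks found: {runs}")
    start, length = runs[0]
    if length != 3:
        raise PrimerFormatError(
            f"degenerate block at offset {start} has length {length}, expected 3"
        )
    return start, DegenerateCodon(primer_sequence[start : start + 3])


# ---------------------------------------------------------------------------
# Plain-text interfaces

LIBRARY_SPEC_COLUMNS = (
    "name",
    "target_codon_index_1based",
    "scheme",
    "upstream_flank",
    "downstream_flank",
)


def read_library_specs(path: str | Path) -> pd.DataFrame:
    """Read a TSV of library specifications and attach built primers.

    Expected columns: name, target_codon_index_1based, scheme,
    upstream_flank, downstream_flank.  A ``primer`` column holding the
    assembled IUPAC sequence is added.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"scheme": str})
    missing = set(LIBRARY_SPEC_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"library spec file is missing columns: {sorted(missing)}")
    frame["primer"] = [
        build_mutagenic_primer(row.upstream_flank, row.scheme, row.downstream_flank).sequence
        for row in frame.itertuples()
    ]
    return frame


def write_primers_fasta(
    primers: Mapping[str, MutagenicPrimer | str] | Iterable[tuple[str, MutagenicPrimer | str]],
    path: str | Path,
) -> None:
    """Write named primers (degenerate IUPAC letters allowed) as FASTA."""
    items = primers.items() if isinstance(primers, Mapping) else primers
    records = [
        SeqRecord(
            Seq(p.sequence if isinstance(p, MutagenicPrimer) else str(p)),
            id=name,
            description="",
        )
        for name, p in items
    ]
    seqio_write(records, str(path), "fasta")
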