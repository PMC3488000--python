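"""Degenerate-codon enumeration, coverage statistics, and primer QC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lovscreen.library_design import (
    IUPAC_DNA,
    CoverageError,
    DegenerateCodon,
    DegenerateLibrary,
    InvalidCodonError,
    PrimerFormatError,
    amino_acid_distribution,
    build_mutagenic_primer,
    coverage_probability,
    expand_degenerate_codon,
    expected_coverage_fraction,
    oversampling_factor,
    read_library_specs,
    required_clones,
    validate_primer,
    write_primers_fasta,
)

# ---------------------------------------------------------------------------
# Codon expansion


@pytest.mark.parametrize(
    "triplet, expected_size",
    [("NNK", 32), ("ATG", 1), ("NNN", 64), ("NNS", 32), ("RRR", 8)],
)
def test_expansion_size(triplet, expected_size):
    assert len(expand_degenerate_codon(triplet)) == expected_size


def test_expansion_concrete_codon_is_itself():
    assert expand_degenerate_codon("ATG") == ("ATG",)


def test_expansion_is_sorted_and_unique():
    expansion = expand_degenerate_codon("NNK")
    assert list(expansion) == sorted(set(expansion))


@pytest.mark.parametrize("bad", ["NN", "NNKX", "NXK", "N-K"])
def test_invalid_triplets_rejected(bad):
    with pytest.raises(InvalidCodonError):
        DegenerateCodon(bad)


def test_invalid_character_names_position():
    with pytest.raises(InvalidCodonError, match="position 1"):
        DegenerateCodon("NXK")


@given(st.text(alphabet=sorted(IUPAC_DNA), min_size=3, max_size=3))
@settings(max_examples=50, derandomize=True)
def test_expansion_size_is_product_of_degeneracies(triplet):
    expected = math.prod(len(IUPAC_DNA[c]) for c in triplet)
    assert len(expand_degenerate_codon(triplet)) == expected


# ---------------------------------------------------------------------------
# Amino-acid distribution


def brute_force_distribution(triplet, include_stop=True):
    """Independent oracle: translate every expanded codon one by one."""
    from Bio.Seq import Seq

    counts = {}
    for codon in expand_degenerate_codon(triplet):
        residue = str(Seq(codon).translate())
        counts[residue] = counts.get(residue, 0) + 1
    if not include_stop:
        counts.pop("*", None)
    total = sum(counts.values())
    return {r: c / total for r, c in counts.items()}


@pytest.mark.parametrize("triplet", ["NNK", "NNN", "NNS", "ATG", "RRY"])
@pytest.mark.parametrize("include_stop", [True, False])
def test_distribution_matches_brute_force_translation(triplet, include_stop):
    expected = brute_force_distribution(triplet, include_stop)
    got = amino_acid_distribution(triplet, include_stop=include_stop)
    assert got.keys() == expected.keys()
    for residue in expected:
        assert got[residue] == pytest.approx(expected[residue], abs=1e-15)


def test_nnk_stop_and_leucine_probabilities():
    dist = amino_acid_distribution("NNK", include_stop=True)
    assert dist["*"] == pytest.approx(1 / 32)  # TAG is the only NNK stop
    assert dist["L"] == pytest.approx(3 / 32)


def test_nnk_covers_all_twenty_residues():
    dist = amino_acid_distribution("NNK", include_stop=False)
    assert len(dist) == 20
    assert all(p > 0 for p in dist.values())
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


def test_atg_is_pure_methionine():
    assert amino_acid_distribution("ATG") == {"M": 1.0}


def test_library_levels():
    codon_lib = DegenerateLibrary(DegenerateCodon("NNK"), level="codon")
    aa_lib = DegenerateLibrary(
        DegenerateCodon("NNK"), level="amino_acid", include_stop=False
    )
    assert len(codon_lib) == 32
    assert len(aa_lib) == 20
    assert sum(codon_lib.variant_probs.values()) == pytest.approx(1.0, abs=1e-12)
    assert sum(aa_lib.variant_probs.values()) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Coverage


def enumerate_coverage(n, probs):
    """Oracle: sum the probability of every covering outcome sequence."""
    m = len(probs)
    total = 0.0
    for outcome in itertools.product(range(m), repeat=n):
        if set(outcome) == set(range(m)):
            total += math.prod(probs[i] for i in outcome)
    return total


SMALL_LIBRARIES = [
    [1.0],
    [0.5, 0.5],
    [0.7, 0.3],
    [1 / 3, 1 / 3, 1 / 3],
    [0.5, 0.3, 0.2],
    [0.6, 0.3, 0.1],
]


@pytest.mark.parametrize("probs", SMALL_LIBRARIES, ids=str)
@pytest.mark.parametrize("n", range(7))
def test_inclusion_exclusion_equals_enumeration(probs, n):
    exact = coverage_probability(n, probs).p_complete
    assert exact == pytest.approx(enumerate_coverage(n, probs), abs=1e-12)


def test_known_small_coverage_values():
    assert coverage_probability(0, [0.5, 0.5]).p_complete == 0.0
    assert coverage_probability(2, [0.5, 0.5]).p_complete == pytest.approx(0.5)
    assert coverage_probability(3, [1 / 3] * 3).p_complete == pytest.approx(6 / 27)


def test_coverage_monotone_in_n_and_reaches_one():
    probs = [1 / 32] * 32
    values = [coverage_probability(n, probs).p_complete for n in range(0, 400, 25)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    n95 = required_clones(probs, 0.95)
    assert coverage_probability(10 * n95, probs).p_complete > 0.999999


def test_monte_carlo_agrees_with_exact_for_nnk():
    probs = [1 / 32] * 32
    for n in (96, 180):
        exact = coverage_probability(n, probs, method="exact")
        mc = coverage_probability(n, probs, method="monte_carlo")
        assert mc.method == "monte_carlo" and mc.mc_se > 0
        se = math.sqrt(exact.p_complete * (1 - exact.p_complete) / 100_000)
        assert abs(mc.p_complete - exact.p_complete) <= 3 * se


def test_required_clones_small_cases():
    assert required_clones([1.0], 0.95) == 1
    assert required_clones([0.5, 0.5], 0.5) == 2


def test_required_clones_nnk_matches_monte_carlo_oracle():
    """The smallest n with 95% complete NNK coverage, cross-checked by
    an independent coupon-collector simulation (1e5 replicates)."""
    probs = [1 / 32] * 32
    n95 = required_clones(probs, 0.95)
    assert n95 == 203  # frozen from the simulation below
    rng = np.random.default_rng(12345)
    for n, side in ((n95 - 1, "below"), (n95, "above")):
        draws = rng.integers(0, 32, size=(100_000, n))
        seen = np.zeros((100_000, 32), dtype=bool)
        seen[np.arange(100_000)[:, None], draws] = True
        p_hat = seen.all(axis=1).mean()
        se = math.sqrt(p_hat * (1 - p_hat) / 100_000)
        exact = coverage_probability(n, probs).p_complete
        assert abs(p_hat - exact) <= 3 * se
        if side == "below":
            assert exact < 0.95
        else:
            assert exact >= 0.95


def test_expected_coverage_fraction_rule_of_thumb():
    # 96 NNK clones give ~95% of variants seen on average, far short of
    # the ~20% complete-coverage probability at the same n.
    assert expected_coverage_fraction(96, [1 / 32] * 32) == pytest.approx(
        1 - (31 / 32) ** 96
    )
    assert expected_coverage_fraction(96, [1 / 32] * 32) > 0.95


def test_coverage_input_validation():
    with pytest.raises(CoverageError):
        coverage_probability(-1, [0.5, 0.5])
    with pytest.raises(CoverageError):
        coverage_probability(3, [0.5, 0.4])
    with pytest.raises(CoverageError):
        required_clones([1.0, 0.0], 0.95)
    with pytest.raises(CoverageError):
        required_clones([0.5, 0.5], 1.5)


# ---------------------------------------------------------------------------
# Oversampling


def test_oversampling_factors():
    assert oversampling_factor(180, "NNK") == pytest.approx(5.625)
    assert oversampling_factor(32, "NNK") == pytest.approx(1.0)
    assert oversampling_factor(64, "NNN") == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Primers (the published F37X and R54X mutagenic oligos)

F37X_PRIMER = "CGTCAACCCGGCCNNKGAGCGCCTGACC"
R54X_PRIMER = "TTCTCTATCAGGACGCANNKTTTCTTCAGGGCGAGG"


def test_build_primer_reproduces_f37x_oligo():
    primer = build_mutagenic_primer("CGTCAACCCGGCC", "NNK", "GAGCGCCTGACC")
    assert primer.sequence == F37X_PRIMER
    assert primer.degenerate_start == 13


def test_build_primer_reproduces_r54x_oligo():
    primer = build_mutagenic_primer("TTCTCTATCAGGACGCA", "NNK", "TTTCTTCAGGGCGAGG")
    assert primer.sequence == R54X_PRIMER
    assert primer.degenerate_start == 17


def test_build_primer_concrete_scheme():
    primer = build_mutagenic_primer("AAAAAAAAAA", "ATG", "TTTTTTTTTT")
    assert primer.degenerate_start == 10
    assert len(expand_degenerate_codon(primer.scheme)) == 1


def test_build_primer_rejects_degenerate_flank():
    with pytest.raises(PrimerFormatError):
        build_mutagenic_primer("CGTCAACCCGGNC", "NNK", "GAGCGCCTGACC")


def test_build_primer_rejects_short_flank():
    with pytest.raises(PrimerFormatError):
        build_mutagenic_primer("CGTCA", "NNK", "GAGCGCCTGACC")


def test_validate_primer_round_trip():
    offset, scheme = validate_primer(F37X_PRIMER)
    assert offset == 13
    assert scheme.triplet == "NNK"


def test_validate_primer_rejects_concrete_amplification_primer():
    with pytest.raises(PrimerFormatError, match="no degenerate block"):
        validate_primer("GGATCCATGATCAACGCAAAACTCCTG")


def test_validate_primer_rejects_multiple_blocks():
    with pytest.raises(PrimerFormatError, match="multiple"):
        validate_primer("AAAAANNKAAAAANNKAAAAA")


def test_validate_primer_rejects_wrong_block_length():
    with pytest.raises(PrimerFormatError, match="length 2"):
        validate_primer("AAAAANKAAAAA")


# ---------------------------------------------------------------------------
# Plain-text interfaces


def test_library_spec_tsv_and_fasta_round_trip(tmp_path):
    spec = tmp_path / "libraries.tsv"
    spec.write_text(
        "name\ttarget_codon_index_1based\tscheme\tupstream_flank\tdownstream_flank\n"
        "F37X\t37\tNNK\tCGTCAACCCGGCC\tGAGCGCCTGACC\n"
    )
    frame = read_library_specs(spec)
    assert frame.loc[0, "primer"] == F37X_PRIMER

    fasta = tmp_path / "primers.fasta"
    write_primers_fasta({"F37X": frame.loc[0, "primer"]}, fasta)
    text = fasta.read_text()
    assert ">F37X" in text and "NNK" in text
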