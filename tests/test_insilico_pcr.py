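"""Amplicon prediction: binding sites, naive and digestion-aware PCR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdsim.insilico_pcr import (
    ADAPTOR,
    TE_PRIMER,
    evaluate_candidate,
    find_binding_sites,
    labeled_pcr,
    naive_insilico_pcr,
    selective_pcr,
)
from tdsim.primer_design import DesignParameters, PrimerCandidate
from tdsim.restriction import ECORI, digest, ligate_adaptors, revcomp, scan_sites
from tdsim.seqio import Genome

from conftest import random_genome


# --- binding sites --------------------------------------------------------


def test_binding_site_plus_strand():
    (site,) = find_binding_sites("TTTTACGTACGTACTTTT", "ACGTACGTAC")
    assert (site.position, site.strand, site.mismatches) == (4, "+", 0)


def test_binding_site_minus_strand():
    primer = "ACGTACGTTC"
    seq = "TTTT" + revcomp(primer) + "TTTT"
    (site,) = find_binding_sites(seq, primer)
    # the primer 5' end maps to the right edge of the top-strand match
    assert (site.position, site.strand) == (4 + len(primer) - 1, "-")


def test_binding_site_anchor_rule():
    primer = "ACGTACGTAC"
    seq = "CCCCACGTACGTAGCCCC"  # mismatch at the primer's 3'-terminal base
    assert find_binding_sites(seq, primer, max_mismatches=1, anchor_len=3) == []
    seq2 = "CCCCAGGTACGTACCCCC"  # mismatch away from the 3' anchor
    (site,) = find_binding_sites(seq2, primer, max_mismatches=1, anchor_len=3)
    assert site.mismatches == 1


def test_binding_site_errors():
    with pytest.raises(ValueError, match="empty"):
        find_binding_sites("ACGT", "")
    with pytest.raises(ValueError, match="longer"):
        find_binding_sites("ACG", "ACGT")


def test_n_never_matches():
    assert find_binding_sites("TTTTACGTACGTNCTTTT", "ACGTACGTAC",
                              max_mismatches=1, anchor_len=3) == []


# --- naive mode -----------------------------------------------------------


def test_naive_span_convention():
    """Span runs from the primer 5' end through the motif's far edge."""
    seq = "TTTT" + "ACGTACGTAC" + "TTTTT" + "GAATTC" + "TTTT"
    g = Genome("g", {"c1": seq})
    amps, n_fw, n_rv = naive_insilico_pcr(g, "ACGTACGTAC")
    assert (n_fw, n_rv) == (1, 0)
    assert amps[0].genomic_span == 25 - 4  # motif ends at 25, primer 5' at 4
    assert amps[0].end_types == (TE_PRIMER, "restriction_site")


def test_naive_no_site_within_cap():
    seq = "TTTT" + "ACGTACGTAC" + "T" * 50 + "GAATTC"
    g = Genome("g", {"c1": seq})
    amps, _, _ = naive_insilico_pcr(g, "ACGTACGTAC", params=DesignParameters(amp_size_max=40))
    assert amps == []


def test_naive_keeps_all_downstream_sites():
    seq = "TTTT" + "ACGTACGTAC" + "TTTTT" + "GAATTC" + "TTT" + "GAATTC" + "TT"
    g = Genome("g", {"c1": seq})
    amps, n_fw, _ = naive_insilico_pcr(g, "ACGTACGTAC")
    assert n_fw == 2
    assert sorted(a.genomic_span for a in amps) == [21, 30]


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_naive_strand_symmetry(seed):
    """Reverse-complementing the genome preserves the span multiset and
    swaps the fw/rv counts."""
    rng = np.random.default_rng(seed)
    g = random_genome(rng, 3000)
    primer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=12)])
    amps, n_fw, n_rv = naive_insilico_pcr(g, primer)
    g_rc = Genome("g", {"c1": revcomp(g.contigs["c1"])})
    amps_rc, n_fw_rc, n_rv_rc = naive_insilico_pcr(g_rc, primer)
    assert (n_fw, n_rv) == (n_rv_rc, n_fw_rc)
    assert sorted(a.genomic_span for a in amps) == sorted(
        a.genomic_span for a in amps_rc
    )


# --- digestion-aware mode -------------------------------------------------


def _assay(genome, primer, params=DesignParameters()):
    frags = ligate_adaptors(digest(genome))
    return frags, selective_pcr(frags, primer, params=params)


def test_selective_known_geometry():
    """A TE-primer site 300 bp from the fragment's right cut yields one
    te_primer->adaptor product with that genomic span."""
    primer = "ACGTTACGGATCACGTTAGC"
    seq = "GAATTC" + "T" * 40 + primer + "A" * (300 - len(primer) - 1) + "GAATTC" + "TT"
    g = Genome("g", {"c1": seq})
    frags, products = _assay(g, primer)
    te = [a for a in products if TE_PRIMER in a.end_types]
    assert len(te) == 1
    # span includes the 4-base overhang regenerated beyond the cut
    assert te[0].genomic_span == 300 + 4
    # tail 20 + 300 to the cut + overhang 4 + adaptor extension 14
    assert te[0].product_length == 20 + 300 + 4 + 14


def test_selective_adaptor_adaptor_product():
    seq = "TT" + "GAATTC" + "A" * 200 + "GAATTC" + "TT"
    g = Genome("g", {"c1": seq})
    _, products = _assay(g, "ACGTTACGGATCACGTTAGC")
    aa = [a for a in products if a.end_types == (ADAPTOR, ADAPTOR)]
    assert len(aa) == 1
    assert aa[0].genomic_span == 206  # top-strand cut to cut


def test_selective_chromosome_end_yields_nothing():
    primer = "ACGTTACGGATCACGTTAGC"
    seq = "T" * 30 + primer + "T" * 30  # no cut site at all
    _, products = _assay(Genome("g", {"c1": seq}), primer)
    assert products == []


def _brute_force_te_products(genome, primer, params):
    """Independent enumeration: each binding site pairs with the nearest
    cut in its extension direction, provided it exists (adaptor ligated)."""
    out = []
    for contig, seq in genome.contigs.items():
        cuts = [s + ECORI.cut_top for s in scan_sites(seq, ECORI)]
        for site in find_binding_sites(seq, primer, params.max_mismatches,
                                       params.anchor_len, contig):
            if site.strand == "+":
                lo, hi = site.position, site.position + len(primer)
            else:
                lo, hi = site.position - len(primer) + 1, site.position + 1
            if any(lo < c < hi for c in cuts):
                continue  # a cut inside the match destroys the site
            if site.strand == "+":
                ahead = [c for c in cuts if c >= hi]
                if not ahead:
                    continue
                # the + primer copies the bottom strand, severed `overhang`
                # beyond the nearest top-strand cut
                span = min(ahead) - site.position + len(ECORI.overhang)
            else:
                behind = [c for c in cuts if c <= lo]
                if not behind:
                    continue
                span = site.position - max(behind) + 1
            if span <= params.amp_size_max:
                out.append((contig, site.position, site.strand, span))
    return sorted(out)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_selective_matches_brute_force(seed):
    """Digestion-aware products equal the (binding site, nearest cut)
    enumeration computed independently of the fragment machinery."""
    rng = np.random.default_rng(seed)
    g = random_genome(rng, int(rng.integers(500, 10_000)))
    seq = g.contigs["c1"]
    start = int(rng.integers(0, len(seq) - 15))
    primer = seq[start : start + 15]  # guaranteed at least one + site
    params = DesignParameters()
    _, products = _assay(g, primer, params)
    te = sorted(
        (a.contig, a.fw_position, a.strand, a.genomic_span)
        for a in products
        if TE_PRIMER in a.end_types
    )
    assert te == _brute_force_te_products(g, primer, params)


def test_selective_primer_site_must_point_at_ligated_end():
    primer = "ACGTTACGGATCACGTTAGC"
    # cut only on the left; + strand site points right at a chromosome end
    seq = "GAATTC" + "T" * 30 + primer + "T" * 30
    _, products = _assay(Genome("g", {"c1": seq}), primer)
    assert [a for a in products if TE_PRIMER in a.end_types] == []
    # the reverse-complement primer points left at the ligated cut
    seq2 = "GAATTC" + "T" * 30 + revcomp(primer) + "T" * 30
    _, products2 = _assay(Genome("g", {"c1": seq2}), primer)
    te = [a for a in products2 if TE_PRIMER in a.end_types]
    assert len(te) == 1 and te[0].strand == "-"


# --- labeled PCR ----------------------------------------------------------


def test_labeled_subset_and_idempotence():
    seq = ("GAATTC" + "A" * 100) * 3 + "ACGTTACGGATCACGTTAGC" + "T" * 50 + "GAATTC"
    g = Genome("g", {"c1": seq})
    _, products = _assay(g, "ACGTTACGGATCACGTTAGC")
    labeled = labeled_pcr(products)
    assert all(a.labeled and TE_PRIMER in a.end_types for a in labeled)
    assert len(labeled) == sum(TE_PRIMER in a.end_types for a in products)
    assert labeled_pcr(labeled) == labeled
    spans = {(a.contig, a.fw_position, a.cut_position) for a in labeled}
    all_spans = {(a.contig, a.fw_position, a.cut_position) for a in products}
    assert spans <= all_spans


# --- candidate evaluation -------------------------------------------------


def test_evaluate_candidate_planted_copies():
    """Three same-strand copies, each with one downstream site inside the
    size cap -> counts 3/0 and identical min/max spans."""
    primer = "ACGTTACGGATCACGTTAGC"
    unit = primer + "T" * 80 + "GAATTC" + "A" * 40
    g = Genome("g", {"c1": ("C" * 20 + unit) * 3})
    params = DesignParameters(amp_size_max=150)  # exclude cross-copy pairs
    cand = evaluate_candidate(g, PrimerCandidate("p", primer), params=params)
    assert (cand.n_amplicons_fw, cand.n_amplicons_rv) == (3, 0)
    assert cand.amp_size_min == 20 + 80 + 6
    assert cand.amp_size_max == 20 + 80 + 6  # all copies identical geometry


def test_evaluate_candidate_no_sites():
    g = Genome("g", {"c1": "T" * 500})
    cand = evaluate_candidate(g, PrimerCandidate("p", "ACGTTACGGATCACGTTAGC"))
    assert (cand.n_amplicons_fw, cand.n_amplicons_rv) == (0, 0)
    assert cand.amp_size_min is None and cand.amp_size_max is None
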