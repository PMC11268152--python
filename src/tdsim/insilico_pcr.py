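"""Amplicon prediction: naive and digestion-aware in-silico PCR.

Two modes with distinct semantics:

* **naive** — the primer-screening mode: every primer binding site is
  paired with every restriction-site occurrence downstream of its 3'
  end within the size cap, ignoring digestion.  This is the mode used
  to compute per-primer amplicon counts and size ranges during design.
* **digestion-aware** (``selective_pcr``) — the assay mode: complete
  digestion means a primer can only be extended to the nearest cut,
  i.e. to the adaptor-ligated end of its own fragment.  Each site
  oriented toward a ligated end yields exactly one TE-primer→adaptor
  product; fragments with two ligated ends additionally amplify as
  adaptor↔adaptor products, which the labeled PCR then discards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .primer_design import DesignParameters, PrimerCandidate
from .restriction import AdaptorDuplex, ECORI, ECORI_ADAPTOR, Fragment, RestrictionEnzyme, revcomp, scan_sites
from .seqio import Genome

TE_PRIMER = "te_primer"
ADAPTOR = "adaptor"
RESTRICTION_SITE = "restriction_site"


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site; ``position`` is the primer 5' end (0-based)."""

    contig: str
    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``genomic_span`` counts genomic bases from the primer 5' end through
    the far edge (motif end in naive mode, template-strand cut in
    digestion-aware mode); ``product_length`` adds tail and adaptor
    chemistry for assay products.
    """

    contig: str
    fw_position: int
    strand: str
    cut_position: int
    genomic_span: int
    product_length: int
    end_types: tuple[str, str]
    labeled: bool = False
    source_primer: str = ""


def find_binding_sites(
    sequence: str,
    primer: str,
    max_mismatches: int = 0,
    anchor_len: int = 3,
    contig: str = "",
) -> list[BindingSite]:
    """Primer occurrences on both strands of ``sequence``.

    The ``anchor_len`` 3'-terminal bases must match exactly; at most
    ``max_mismatches`` mismatches elsewhere.  N never matches.
    """
    if not primer:
        raise ValueError("empty primer")
    L = len(primer)
    if L > len(sequence):
        raise ValueError("primer longer than sequence")
    sites: list[BindingSite] = []
    rc = revcomp(primer)
    if max_mismatches == 0:
        for pat, strand in ((primer, "+"), (rc, "-")):
            start = 0
            while (i := sequence.find(pat, start)) != -1:
                pos5 = i if strand == "+" else i + L - 1
                sites.append(BindingSite(contig, pos5, strand, 0))
                start = i + 1
    else:
        anchor_len = min(anchor_len, L)
        for pat, strand in ((primer, "+"), (rc, "-")):
            # on the - strand the primer 3' end maps to the left edge of
            # the top-strand match
            anchor = range(L - anchor_len, L) if strand == "+" else range(anchor_len)
            for i in range(len(sequence) - L + 1):
                win = sequence[i : i + L]
                mm = sum(a != b or b == "N" for a, b in zip(pat, win))
                if mm > max_mismatches:
                    continue
                if any(pat[j] != win[j] or win[j] == "N" for j in anchor):
                    continue
                pos5 = i if strand == "+" else i + L - 1
                sites.append(BindingSite(contig, pos5, strand, mm))
    return sorted(sites, key=lambda s: (s.position, s.strand))


def naive_insilico_pcr(
    genome: Genome,
    fw_primer: str | PrimerCandidate,
    enzyme: RestrictionEnzyme = ECORI,
    params: DesignParameters = DesignParameters(),
) -> tuple[list[Amplicon], int, int]:
    """Screen-mode PCR with the restriction site itself as reverse primer.

    Returns ``(amplicons, n_fw, n_rv)`` where the counts split products
    by primer-site strand.  Every downstream site within the size cap
    produces one amplicon; ``genomic_span`` runs from the primer 5' end
    through the far edge of the recognition motif, inclusive.
    """
    core = fw_primer.core_seq if isinstance(fw_primer, PrimerCandidate) else fw_primer
    name = fw_primer.name if isinstance(fw_primer, PrimerCandidate) else ""
    L, mlen = len(core), len(enzyme.recognition)
    seen: set[tuple] = set()
    amplicons: list[Amplicon] = []
    for contig, seq in genome.contigs.items():
        motifs = scan_sites(seq, enzyme)
        for site in find_binding_sites(
            seq, core, params.max_mismatches, params.anchor_len, contig
        ):
            if site.strand == "+":
                pairs = (
                    (m, m + mlen - site.position)
                    for m in motifs
                    if m >= site.position + L
                )
            else:
                pairs = (
                    (m, site.position - m + 1)
                    for m in motifs
                    if m + mlen <= site.position - L + 1
                )
            for m, span in pairs:
                if span > params.amp_size_max:
                    continue
                key = (contig, site.position, m, site.strand)
                if key in seen:
                    continue
                seen.add(key)
                amplicons.append(
                    Amplicon(
                        contig=contig,
                        fw_position=site.position,
                        strand=site.strand,
                        cut_position=m,
                        genomic_span=span,
                        product_length=span,
                        end_types=(TE_PRIMER, RESTRICTION_SITE),
                        source_primer=name,
                    )
                )
    n_fw = sum(a.strand == "+" for a in amplicons)
    n_rv = sum(a.strand == "-" for a in amplicons)
    return amplicons, n_fw, n_rv


def selective_pcr(
    fragments: Sequence[Fragment],
    tailed_primer: PrimerCandidate | str,
    enzyme: RestrictionEnzyme = ECORI,
    adaptor: AdaptorDuplex = ECORI_ADAPTOR,
    params: DesignParameters = DesignParameters(),
) -> list[Amplicon]:
    """Digestion-aware first PCR on adaptor-ligated fragments.

    Each core-primer site oriented toward a ligated fragment end yields
    one TE-primer→adaptor product ending at that cut; fragments ligated
    at both ends also amplify adaptor↔adaptor.  The genomic span includes
    the regenerated overhang; product length adds the tail and the
    adaptor extension beyond the overhang.
    """
    if isinstance(tailed_primer, PrimerCandidate):
        core = tailed_primer.core_seq
        name = tailed_primer.name
        tail_len = (
            len(tailed_primer.tailed_seq) - len(core)
            if tailed_primer.tailed_seq
            else len(params.tail)
        )
    else:
        core = tailed_primer
        name = ""
        tail_len = len(params.tail)
    ov = len(enzyme.overhang)
    ext = adaptor.extension_beyond_overhang
    seen: set[tuple] = set()
    out: list[Amplicon] = []
    for frag in fragments:
        flen = len(frag)
        sites = (
            find_binding_sites(
                frag.sequence, core, params.max_mismatches, params.anchor_len,
                frag.contig,
            )
            if flen >= len(core)
            else []
        )
        for site in sites:
            # span runs to the cut of the strand the primer copies: a +
            # primer extends along the bottom strand, severed `overhang`
            # beyond the top-strand fragment boundary; a - primer extends
            # along the top strand, severed at the boundary itself.  This
            # keeps spans strand-symmetric.
            if site.strand == "+":
                if not frag.right_adaptor:
                    continue
                d = flen - site.position + ov
                cut = frag.span[1]
            else:
                if not frag.left_adaptor:
                    continue
                d = site.position + 1
                cut = frag.span[0]
            if d > params.amp_size_max:
                continue
            gpos = frag.span[0] + site.position
            key = (frag.contig, gpos, cut, site.strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                Amplicon(
                    contig=frag.contig,
                    fw_position=gpos,
                    strand=site.strand,
                    cut_position=cut,
                    genomic_span=d,
                    product_length=tail_len + d + ext,
                    end_types=(TE_PRIMER, ADAPTOR),
                    source_primer=name,
                )
            )
        if frag.left_adaptor and frag.right_adaptor and flen <= params.amp_size_max:
            out.append(
                Amplicon(
                    contig=frag.contig,
                    fw_position=frag.span[0],
                    strand="+",
                    cut_position=frag.span[1],
                    genomic_span=flen,
                    product_length=len(adaptor.strand_a) + flen + len(adaptor.strand_b),
                    end_types=(ADAPTOR, ADAPTOR),
                    source_primer=name,
                )
            )
    return out


def labeled_pcr(
    selective_products: Iterable[Amplicon],
    params: DesignParameters = DesignParameters(),
) -> list[Amplicon]:
    """Second PCR with the fluorescent tail primer.

    Only products carrying a TE-primer end (hence the tail) re-amplify;
    adaptor↔adaptor products drop out.  No new amplicons are created and
    the operation is idempotent.
    """
    return [
        replace(a, labeled=True)
        for a in selective_products
        if TE_PRIMER in a.end_types
    ]


def evaluate_candidate(
    genome: Genome,
    candidate: PrimerCandidate,
    enzyme: RestrictionEnzyme = ECORI,
    params: DesignParameters = DesignParameters(),
) -> PrimerCandidate:
    """Fill the design-report statistics via naive in-silico PCR."""
    amps, n_fw, n_rv = naive_insilico_pcr(genome, candidate, enzyme, params)
    spans = [a.genomic_span for a in amps]
    candidate.n_amplicons_fw = n_fw
    candidate.n_amplicons_rv = n_rv
    candidate.amp_size_min = min(spans) if spans else None
    candidate.amp_size_max = max(spans) if spans else None
    return candidate
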