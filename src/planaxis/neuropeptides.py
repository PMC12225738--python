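"""Rule-based neuropeptide prediction from precursor proteins.

Mature cnidarian neuropeptides are excised from secreted precursor
proteins by prohormone convertases at dibasic sites (adjacent K/R pairs)
and then post-translationally modified: a C-terminal glycine preceding
the cleavage site is converted to a C-terminal amide (e.g., HFRIG ->
HFRI-amide), and an N-terminal glutamine cyclizes to pyroglutamate
(QYF -> pyroGlu-YF). Some precursors instead carry tandem repeats of a
short peptide motif between cleavage-like sites without the amidation
glycine; these repeat products are emitted non-amidated.

The scanner implements exactly those rules:

* dibasic sites {KR, RR, KK, RK}, scanned left to right without overlap
  (within a run like ``KRR`` the leftmost pair wins and scanning resumes
  after it);
* candidate products are the inter-site segments downstream of the
  signal-peptide cleavage position, trimmed of the amidation glycine and
  length-bounded to plausible neuropeptide sizes;
* a tandem repeat motif search over k-mers (homopolymers excluded) that
  allows a short cleavage-bearing linker between copies;
* a precursor is flagged neuropeptide-like iff it has a signal peptide
  and yields at least two products of which at least one is amidated.

Precursors without a signal peptide produce no products — a secreted
precursor is part of the definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PrecursorProtein",
    "CleavageProduct",
    "ScanConfig",
    "find_cleavage_sites",
    "excise_products",
    "find_repeat_motif",
    "scan_precursor",
    "scan_fasta",
]

DIBASIC_MOTIFS = ("KR", "RR", "KK", "RK")


@dataclass(frozen=True)
class PrecursorProtein:
    id: str
    sequence: str
    has_signal_peptide: bool = False
    signal_cleavage_pos: int | None = None

    def __post_init__(self) -> None:
        if self.signal_cleavage_pos is not None and self.sequence:
            if not (0 <= self.signal_cleavage_pos < len(self.sequence)):
                raise ValueError("signal_cleavage_pos outside the sequence")


@dataclass(frozen=True)
class CleavageProduct:
    """A predicted mature peptide.

    ``start``/``end`` are 0-based half-open coordinates of the (trimmed)
    peptide on the precursor, so ``sequence[start:end] == peptide``.
    ``amidated`` means the pre-trim segment ended in a glycine followed by
    a cleavage site or the terminus; ``pyro_glu`` that it starts with Q.
    """

    peptide: str
    start: int
    end: int
    amidated: bool
    pyro_glu: bool
    left_site: str | None = None
    right_site: str | None = None


@dataclass
class ScanConfig:
    site_motifs: tuple[str, ...] = DIBASIC_MOTIFS
    min_len: int = 3          # after glycine trimming
    max_len: int = 50
    default_signal_len: int = 20  # stub when the flag is set without a position
    repeat_k_range: tuple[int, int] = (4, 8)
    min_repeats: int = 3
    max_linker: int = 4


@dataclass
class PrecursorReport:
    precursor: PrecursorProtein
    sites: list[tuple[int, int]] = field(default_factory=list)
    products: list[CleavageProduct] = field(default_factory=list)
    repeat_motif: tuple[str, int, list[int]] | None = None
    neuropeptide_like: bool = False
    no_products_reason: str | None = None


def find_cleavage_sites(
    p: PrecursorProtein, site_motifs: tuple[str, ...] = DIBASIC_MOTIFS
) -> list[tuple[int, int]]:
    """Non-overlapping dibasic site positions, scanned left to right.

    Returns (start, end) half-open spans of length 2. In an overlapping
    run such as ``KRR`` the leftmost pair is taken and scanning resumes
    after it (``KRRK`` -> sites at 0-2 and 2-4).
    """
    seq = p.sequence
    sites: list[tuple[int, int]] = []
    i = 0
    while i < len(seq) - 1:
        if seq[i : i + 2] in site_motifs:
            sites.append((i, i + 2))
            i += 2
        else:
            i += 1
    return sites


def excise_products(
    p: PrecursorProtein,
    sites: list[tuple[int, int]],
    config: ScanConfig | None = None,
) -> list[CleavageProduct]:
    """Peptide products from the inter-site segments of a precursor.

    Candidate segments run from the signal cleavage position (or a
    ``default_signal_len``-residue stub when the flag is set without a
    position) to the first site, between consecutive sites, and from the
    last site to the terminus. A terminal glycine right before a site or
    the terminus is trimmed and marks amidation; a leading glutamine marks
    pyroglutamate. Products shorter than ``min_len`` (after trimming) or
    longer than ``max_len`` are discarded. Precursors without a signal
    peptide yield no products.
    """
    config = config or ScanConfig()
    if not p.has_signal_peptide:
        return []
    start0 = (
        p.signal_cleavage_pos
        if p.signal_cleavage_pos is not None
        else min(config.default_signal_len, len(p.sequence))
    )
    seq = p.sequence
    bounds: list[tuple[int, int, str | None, str | None]] = []
    prev_end, prev_motif = start0, None
    for s, e in sites:
        if s >= prev_end:
            bounds.append((prev_end, s, prev_motif, seq[s:e]))
            prev_end, prev_motif = e, seq[s:e]
        elif e > prev_end:
            prev_end, prev_motif = e, seq[s:e]
    bounds.append((prev_end, len(seq), prev_motif, None))

    products: list[CleavageProduct] = []
    for left, right, lmotif, rmotif in bounds:
        if right <= left:
            continue
        segment = seq[left:right]
        amidated = segment.endswith("G")
        peptide = segment[:-1] if amidated else segment
        if not (config.min_len <= len(peptide) <= config.max_len):
            continue
        products.append(
            CleavageProduct(
                peptide=peptide,
                start=left,
                end=left + len(peptide),
                amidated=amidated,
                pyro_glu=peptide.startswith("Q"),
                left_site=lmotif,
                right_site=rmotif,
            )
        )
    return products


def _is_homopolymer(kmer: str) -> bool:
    return len(set(kmer)) == 1


def find_repeat_motif(
    p: PrecursorProtein, config: ScanConfig | None = None
) -> tuple[str, int, list[int]] | None:
    """Most-repeated tandem k-mer motif, if it reaches ``min_repeats``.

    For every k in ``repeat_k_range`` and every start position, copies of
    the k-mer are chained when adjacent or separated by a linker of at
    most ``max_linker`` residues that contains a cleavage motif.
    Homopolymer k-mers are excluded (low-complexity false positives), and
    so are k-mers overlapping a detected cleavage site: the repeat unit
    is the mature peptide between sites, never a stretch straddling the
    peptide-plus-site cassette. Ties favor the larger k, then the
    leftmost start.
    """
    config = config or ScanConfig()
    seq = p.sequence
    k_lo, k_hi = config.repeat_k_range
    in_site = bytearray(len(seq))
    for s, e in find_cleavage_sites(p, config.site_motifs):
        for i in range(s, e):
            in_site[i] = 1
    best: tuple[int, int, int, list[int]] | None = None  # (count, k, -start, positions)
    for k in range(k_lo, k_hi + 1):
        for start in range(0, len(seq) - k + 1):
            motif = seq[start : start + k]
            if _is_homopolymer(motif):
                continue
            if any(in_site[start : start + k]):
                continue
            positions = [start]
            pos = start + k
            while True:
                if seq[pos : pos + k] == motif:
                    positions.append(pos)
                    pos += k
                    continue
                advanced = False
                for g in range(2, config.max_linker + 1):
                    linker = seq[pos : pos + g]
                    if len(linker) < g:
                        break
                    has_site = any(
                        linker[i : i + 2] in config.site_motifs
                        for i in range(len(linker) - 1)
                    )
                    if has_site and seq[pos + g : pos + g + k] == motif:
                        positions.append(pos + g)
                        pos += g + k
                        advanced = True
                        break
                if not advanced:
                    break
            count = len(positions)
            if count >= config.min_repeats:
                key = (count, k, -start)
                if best is None or key > (best[0], best[1], best[2]):
                    best = (count, k, -start, positions)
    if best is None:
        return None
    count, k, neg_start, positions = best
    start = -neg_start
    return seq[start : start + k], count, positions


def scan_precursor(
    p: PrecursorProtein, config: ScanConfig | None = None
) -> PrecursorReport:
    """Full scan: sites, products, repeat motif and the summary flag.

    ``neuropeptide_like`` requires a signal peptide, at least two products
    and at least one amidated product.
    """
    config = config or ScanConfig()
    report = PrecursorReport(precursor=p)
    if not p.sequence:
        report.no_products_reason = "empty sequence"
        return report
    report.sites = find_cleavage_sites(p, config.site_motifs)
    report.products = excise_products(p, report.sites, config)
    if not p.has_signal_peptide:
        report.no_products_reason = "no signal peptide"
    report.repeat_motif = find_repeat_motif(p, config)
    n_amidated = sum(1 for pr in report.products if pr.amidated)
    report.neuropeptide_like = (
        p.has_signal_peptide and len(report.products) >= 2 and n_amidated >= 1
    )
    return report


def scan_fasta(
    precursors: list[PrecursorProtein], config: ScanConfig | None = None
) -> pd.DataFrame:
    """Scan many precursors into one tidy report table."""
    rows = []
    for p in precursors:
        rep = scan_precursor(p, config)
        motif, count = (rep.repeat_motif[0], rep.repeat_motif[1]) if rep.repeat_motif else ("", 0)
        if not rep.products:
            rows.append({
                "precursor_id": p.id, "peptide": "", "start": -1, "end": -1,
                "amidated": False, "pyro_glu": False, "motif": motif,
                "motif_count": count, "neuropeptide_like": rep.neuropeptide_like,
            })
        for pr in rep.products:
            rows.append({
                "precursor_id": p.id, "peptide": pr.peptide, "start": pr.start,
                "end": pr.end, "amidated": pr.amidated, "pyro_glu": pr.pyro_glu,
                "motif": motif, "motif_count": count,
                "neuropeptide_like": rep.neuropeptide_like,
            })
    return pd.DataFrame(
        rows,
        columns=["precursor_id", "peptide", "start", "end", "amidated",
                 "pyro_glu", "motif", "motif_count", "neuropeptide_like"],
    )
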