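"""Comparative prediction of C→U / U→C RNA editing sites in organellar CDS.

A query coding sequence is translated codon by codon and aligned (as
protein) against reference proteins of the same gene from related species.
Wherever the query residue differs from the reference consensus and a
single C→U or U→C substitution at one codon position recreates the
consensus residue, an editing site is predicted and its codon effect
classified — including ORF-restoring removal of internal stops, start-codon
gain by ACG→AUG, and stop-codon gain where the references end.  Counts are
aggregated into the summary statistics used to compare organelles (percent
C→U, sites per CDS bp, density ratios).

Codons are handled as DNA (T for U); directions are reported as "C>U" and
"U>C".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

C2U = "C>U"
U2C = "U>C"

EFFECTS = ("silent", "missense", "start_gain", "stop_gain", "stop_loss", "orf_restoring")


class EditingError(ValueError):
    pass


@dataclass(frozen=True)
class EditingSite:
    gene: str
    cds_pos: int  # 0-based position in the CDS
    codon_index: int
    codon_pos: int  # 0, 1 or 2
    direction: str  # C>U or U>C
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    effect: str

    def __post_init__(self) -> None:
        if self.direction not in (C2U, U2C):
            raise EditingError(f"bad direction {self.direction!r}")
        if self.effect not in EFFECTS:
            raise EditingError(f"bad effect {self.effect!r}")
        diffs = [
            i for i in range(3) if self.codon_before[i] != self.codon_after[i]
        ]
        if diffs != [self.codon_pos]:
            raise EditingError("codon_after must differ at exactly codon_pos")
        before, after = self.codon_before[self.codon_pos], self.codon_after[self.codon_pos]
        if (before, after) != (("C", "T") if self.direction == C2U else ("T", "C")):
            raise EditingError("codon change inconsistent with direction")


def _round1(x) -> float:
    return float(Decimal(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EditingSummary:
    """Aggregated editing-site statistics; percentages are always derived
    from the stored counts (never stored independently)."""

    n_c2u: int
    n_u2c: int
    total_cds_len: int
    per_gene: "pd.DataFrame | None" = None

    def __post_init__(self) -> None:
        if self.n_c2u < 0 or self.n_u2c < 0:
            raise EditingError("negative counts")

    @property
    def n_total(self) -> int:
        return self.n_c2u + self.n_u2c

    @property
    def pct_c2u(self) -> float | None:
        return None if self.n_total == 0 else _round1(100 * self.n_c2u / self.n_total)

    @property
    def pct_u2c(self) -> float | None:
        return None if self.n_total == 0 else _round1(100 * self.n_u2c / self.n_total)

    @property
    def density(self) -> float:
        if self.total_cds_len <= 0:
            raise EditingError("total CDS length must be positive")
        return self.n_total / self.total_cds_len


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _translate_codons(cds: str, table_id: int) -> list[str]:
    table = unambiguous_dna_by_id[table_id]
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in table.stop_codons:
            aas.append("*")
        else:
            try:
                aas.append(table.forward_table[codon])
            except KeyError:
                aas.append("X")
    return aas


_aligner = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def _map_reference(query_aa: str, ref_aa: str):
    """Align two protein strings; return dict query-index -> ref residue
    (indel columns absent) and the alignment identity."""
    if query_aa == ref_aa:
        return {i: c for i, c in enumerate(ref_aa)}, 1.0
    aligner = _get_aligner()
    aln = aligner.align(query_aa, ref_aa)[0]
    mapping = {}
    matches = 0
    columns = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for off in range(qe - qs):
            qi, ri = qs + off, rs + off
            mapping[qi] = ref_aa[ri]
            columns += 1
            if query_aa[qi] == ref_aa[ri]:
                matches += 1
    identity = matches / columns if columns else 0.0
    return mapping, identity


def _single_edit_candidates(codon: str):
    """All single C<->T substitutions of a codon: (pos, direction, new codon)."""
    for pos in range(3):
        base = codon[pos]
        if base == "C":
            yield pos, C2U, codon[:pos] + "T" + codon[pos + 1 :]
        elif base == "T":
            yield pos, U2C, codon[:pos] + "C" + codon[pos + 1 :]


def _classify(aa_before, aa_after, codon_index, codon_before, codon_after, n_codons):
    internal = 0 < codon_index < n_codons - 1
    if aa_before == "*" and aa_after != "*" and internal:
        return "orf_restoring"
    if aa_before == "*" and aa_after != "*":
        return "stop_loss"
    if aa_after == "*":
        return "stop_gain"
    if codon_index == 0 and codon_before == "ACG" and codon_after == "ATG":
        return "start_gain"
    if aa_before == aa_after:
        return "silent"
    return "missense"


def predict_editing_sites(
    query_cds: str,
    reference_proteins: list[str],
    gene: str = "gene",
    genetic_code: int = 1,
    min_ref_identity: float = 0.5,
) -> list[EditingSite]:
    """Predict C→U / U→C sites in a CDS against reference proteins.

    Per codon the strict-majority reference residue is the consensus (ties
    give no call); a site is emitted when the query residue differs and a
    single C↔U substitution at one codon position yields the consensus.
    References whose translated alignment identity falls below
    ``min_ref_identity`` are ignored.  Direction C→U is preferred over U→C
    and earlier codon positions over later when several single edits reach
    the consensus.
    """
    query_cds = query_cds.upper().replace("U", "T")
    if not reference_proteins:
        raise EditingError(f"{gene}: no reference proteins")
    if len(query_cds) % 3:
        raise EditingError(
            f"{gene}: CDS length {len(query_cds)} not divisible by 3"
        )
    q_aa = "".join(_translate_codons(query_cds, genetic_code))
    maps = []
    for ref in reference_proteins:
        ref = ref.upper().rstrip("*") + "*"  # align against an explicit stop
        mapping, identity = _map_reference(q_aa, ref)
        if identity >= min_ref_identity:
            maps.append(mapping)
    if not maps:
        raise EditingError(
            f"{gene}: no reference aligns at ≥{min_ref_identity:.0%} identity"
        )
    n_codons = len(q_aa)
    sites = []
    for ci in range(n_codons):
        votes: dict[str, int] = {}
        for mapping in maps:
            r = mapping.get(ci)
            if r is not None:
                votes[r] = votes.get(r, 0) + 1
        if not votes:
            continue
        best = max(votes.values())
        winners = [aa for aa, v in votes.items() if v == best]
        if len(winners) != 1 or 2 * best <= sum(votes.values()):
            continue  # no strict majority: no call
        consensus = winners[0]
        if q_aa[ci] == consensus:
            continue
        codon = query_cds[3 * ci : 3 * ci + 3]
        cands = []
        for pos, direction, new_codon in _single_edit_candidates(codon):
            new_aa = _translate_codons(new_codon, genetic_code)[0]
            if new_aa == consensus:
                cands.append((0 if direction == C2U else 1, pos, direction, new_codon, new_aa))
        if not cands:
            continue
        _, pos, direction, new_codon, new_aa = min(cands)
        sites.append(
            EditingSite(
                gene=gene,
                cds_pos=3 * ci + pos,
                codon_index=ci,
                codon_pos=pos,
                direction=direction,
                codon_before=codon,
                codon_after=new_codon,
                aa_before=q_aa[ci],
                aa_after=new_aa,
                effect=_classify(q_aa[ci], new_aa, ci, codon, new_codon, n_codons),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_editing(sites_or_counts, total_cds_len: int, gene_lengths=None) -> EditingSummary:
    """Build an EditingSummary from a list of EditingSite or an
    (n_c2u, n_u2c) tuple of counts.

    With sites, a per-gene table (gene, n_sites, cds_len, pct_altered) is
    attached when ``gene_lengths`` (gene -> CDS bp) is given.
    """
    import pandas as pd

    if isinstance(sites_or_counts, tuple):
        n_c2u, n_u2c = sites_or_counts
        return EditingSummary(n_c2u=n_c2u, n_u2c=n_u2c, total_cds_len=total_cds_len)
    sites = list(sites_or_counts)
    n_c2u = sum(1 for s in sites if s.direction == C2U)
    n_u2c = sum(1 for s in sites if s.direction == U2C)
    per_gene = None
    if gene_lengths is not None:
        rows = []
        for g, glen in gene_lengths.items():
            k = sum(1 for s in sites if s.gene == g)
            rows.append(
                {
                    "gene": g,
                    "n_sites": k,
                    "cds_len": glen,
                    "pct_altered": _round1(100 * k / glen) if glen else None,
                }
            )
        per_gene = pd.DataFrame(rows)
    return EditingSummary(
        n_c2u=n_c2u, n_u2c=n_u2c, total_cds_len=total_cds_len, per_gene=per_gene
    )


def editing_density_ratio(summaryA: EditingSummary, summaryB: EditingSummary) -> float:
    """densityA / densityB, rounded half-up to one decimal."""
    if summaryB.density == 0:
        raise EditingError("denominator summary has zero editing density")
    return _round1(summaryA.density / summaryB.density)


def sites_table(sites) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "cds_pos": s.cds_pos,
                "codon_index": s.codon_index,
                "codon_pos": s.codon_pos,
                "direction": s.direction,
                "codon_before": s.codon_before,
                "codon_after": s.codon_after,
                "aa_before": s.aa_before,
                "aa_after": s.aa_after,
                "effect": s.effect,
            }
            for s in sites
        ]
    )
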