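"""Two-stage integration of copy-number regions with miRNA expression.

Stage one maps differentially expressed miRNAs onto recurrent copy-number
regions and classifies direction concordance: an up-regulated miRNA inside a
gained region, or a down-regulated miRNA inside a lost region, is concordant
— copy number is then a plausible driver of the expression change.  Stage two
builds a consensus target-gene set per miRNA (a gene must be predicted by at
least two of three databases), intersects it with the genes resident in the
recurrent regions, and ranks genes by how many of the selected miRNAs target
them.  A direction comparison between two DE lists (e.g., this cohort versus
an external cohort) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cna import RecurrentRegion
from .expression import DeRecord


def normalize_mirna_id(mirna_id: str) -> str:
    """Case-fold and strip the 'hsa-' species prefix for cross-table joins."""
    mid = mirna_id.strip().casefold()
    if mid.startswith("hsa-"):
        mid = mid[4:]
    return mid


@dataclass(frozen=True)
class IntegrationRecord:
    """One DE miRNA joined to one overlapping recurrent region."""

    mirna_id: str
    log2_fc: float
    de_direction: str  # up | down
    region: RecurrentRegion
    cna_direction: str  # gain | loss

    @property
    def concordant(self) -> bool:
        return classify_concordance(self.de_direction, self.cna_direction) == "concordant"


@dataclass(frozen=True)
class IntegrationSummary:
    n_de: int
    n_mapped: int
    n_concordant: int
    mapped_percent: float  # n_mapped / n_de, one-decimal percent
    concordant_percent: float  # n_concordant / n_mapped, one-decimal percent


@dataclass(frozen=True)
class GeneHit:
    """A consensus target gene residing in a recurrent copy-number region."""

    gene_id: str
    targeting_mirnas: frozenset[str]
    in_cna: bool
    cna_direction: str | None = None

    @property
    def n_mirnas(self) -> int:
        return len(self.targeting_mirnas)


def classify_concordance(de_direction: str, cna_direction: str) -> str:
    """'concordant' iff (up, gain) or (down, loss); 'discordant' otherwise."""
    if de_direction not in ("up", "down"):
        raise ValueError(f"bad DE direction {de_direction!r}")
    if cna_direction not in ("gain", "loss"):
        raise ValueError(f"bad CNA direction {cna_direction!r}")
    concordant = (de_direction == "up") == (cna_direction == "gain")
    return "concordant" if concordant else "discordant"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention for percentages)."""
    factor = 10**decimals
    scaled = x * factor
    rounded = int(scaled + 0.5) if scaled >= 0 else -int(-scaled + 0.5)
    return rounded / factor


def integrate(
    de_records: list[DeRecord],
    feature_hits: dict[str, list[RecurrentRegion]],
) -> tuple[list[IntegrationRecord], IntegrationSummary]:
    """Join DE miRNAs to the recurrent regions they reside in.

    Produces one record per (DE miRNA, overlapped region) pair; a miRNA
    spanning two regions yields two records but counts once in ``n_mapped``.
    A miRNA is counted concordant when at least one of its records is
    concordant.  Percentages are reported to one decimal, rounded half away
    from zero.
    """
    if not de_records:
        raise ValueError("empty DE list")
    hits_by_norm = {normalize_mirna_id(fid): (fid, regs) for fid, regs in feature_hits.items()}

    records: list[IntegrationRecord] = []
    mapped: set[str] = set()
    concordant: set[str] = set()
    for de in de_records:
        key = normalize_mirna_id(de.feature_id)
        if key not in hits_by_norm:
            continue
        mapped.add(key)
        for region in hits_by_norm[key][1]:
            rec = IntegrationRecord(
                mirna_id=de.feature_id,
                log2_fc=de.log2_fc,
                de_direction=de.direction,
                region=region,
                cna_direction=region.direction,
            )
            records.append(rec)
            if rec.concordant:
                concordant.add(key)

    n_de = len(de_records)
    summary = IntegrationSummary(
        n_de=n_de,
        n_mapped=len(mapped),
        n_concordant=len(concordant),
        mapped_percent=round_half_away(100.0 * len(mapped) / n_de),
        concordant_percent=(
            round_half_away(100.0 * len(concordant) / len(mapped)) if mapped else 0.0
        ),
    )
    return records, summary


def consensus_targets(
    db_tables: list[pd.DataFrame], min_dbs: int = 2
) -> dict[str, frozenset[str]]:
    """Genes predicted for a miRNA by at least ``min_dbs`` of three databases.

    Tables carry columns ``mirna_id, gene_id``; duplicate rows within one
    table are deduplicated silently, and miRNA ids are matched after prefix
    normalization.
    """
    if len(db_tables) != 3:
        raise ValueError("exactly three target databases expected")
    if min_dbs not in (1, 2, 3):
        raise ValueError("min_dbs must be 1, 2 or 3")
    counts: dict[tuple[str, str], int] = {}
    display: dict[str, str] = {}
    for table in db_tables:
        pairs = {
            (normalize_mirna_id(m), g)
            for m, g in zip(table["mirna_id"], table["gene_id"])
        }
        for m_raw in table["mirna_id"]:
            display.setdefault(normalize_mirna_id(m_raw), m_raw)
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1

    result: dict[str, set[str]] = {}
    for (m, g), n in counts.items():
        if n >= min_dbs:
            result.setdefault(display[m], set()).add(g)
    return {m: frozenset(g) for m, g in result.items()}


def intersect_with_cna_genes(
    consensus: dict[str, frozenset[str]],
    cna_genes: dict[str, str],
) -> list[GeneHit]:
    """Consensus target genes that also lie in recurrent copy-number regions.

    ``cna_genes`` maps gene id to the direction of the region it resides in.
    Returns hits sorted by number of targeting miRNAs descending, then gene
    id ascending.
    """
    if not consensus:
        raise ValueError("consensus target map is empty")
    targeting: dict[str, set[str]] = {}
    for mirna, genes in consensus.items():
        for gene in genes:
            targeting.setdefault(gene, set()).add(mirna)
    hits = [
        GeneHit(
            gene_id=gene,
            targeting_mirnas=frozenset(mirnas),
            in_cna=True,
            cna_direction=cna_genes[gene],
        )
        for gene, mirnas in targeting.items()
        if gene in cna_genes
    ]
    hits.sort(key=lambda h: (-h.n_mirnas, h.gene_id))
    return hits


def compare_de_lists(
    list_a: list[DeRecord], list_b: list[DeRecord]
) -> tuple[list[str], list[str], int, int]:
    """Intersect two DE lists and count direction agreement.

    Ids are matched after prefix normalization.  Returns (common ids,
    same-direction ids, n_common, n_same_direction); ids are reported in
    list-a spelling, sorted.
    """
    a = {normalize_mirna_id(r.feature_id): r for r in list_a}
    b = {normalize_mirna_id(r.feature_id): r for r in list_b}
    common_keys = sorted(set(a) & set(b))
    common = [a[k].feature_id for k in common_keys]
    same = [
        a[k].feature_id
        for k in common_keys
        if (a[k].log2_fc > 0) == (b[k].log2_fc > 0)
    ]
    return common, same, len(common), len(same)
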