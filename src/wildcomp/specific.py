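"""Genotype-specific (presence/absence variation) gene classification.

Three-step procedure for genes of genotype A against genotype B:

1. cross-placement — each A cDNA is aligned to the B genome; genes with a
   placement at >= 80% identity and >= 50% coverage are ``placed``, the
   rest are PAV ``candidate`` genes;
2. synteny exclusion — candidates whose gene sits in a syntenic block are
   demoted to ``syntenic_excluded`` (a collinear context evidences a
   homologous locus the aligner missed);
3. read-coverage confirmation — B's reads are mapped onto the A genome;
   candidates whose gene body is covered over less than half its length
   are promoted to ``high_confidence_specific``.  Substantial coverage by
   the other genotype's reads evidences the locus is present there, so
   such candidates stay unconfirmed.

Swapping the genotypes runs the mirror analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import DEFAULT_SCORING, Scoring, map_cdna
from .io import GenomeAnnotation, Read, WildcompError
from .variants import PlacementSet, depth_profile, map_reads


class SpecificGeneError(WildcompError):
    pass


@dataclass(frozen=True)
class CoverageProfile:
    gene_id: str
    gene_length: int
    covered_bp: int

    @property
    def covered_fraction(self) -> float:
        return self.covered_bp / self.gene_length


@dataclass(frozen=True)
class SpecificGeneCall:
    """One gene's PAV classification with its evidence trail."""

    gene_id: str
    status: str  # placed | syntenic_excluded | candidate | high_confidence_specific
    best_identity: float | None = None
    best_coverage: float | None = None
    covered_fraction: float | None = None


def find_candidates(
    cdnas_A: dict[str, str],
    genome_B: GenomeAnnotation,
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[SpecificGeneCall]:
    """Step 1: genes whose cDNA fails to place on the other genome."""
    if not cdnas_A:
        raise SpecificGeneError("empty cDNA set")
    placements, unplaced = map_cdna(
        cdnas_A, genome_B, min_identity=min_identity, min_coverage=min_coverage,
        scoring=scoring,
    )
    best: dict[str, tuple[float, float]] = {}
    for aln in placements:
        cur = best.get(aln.query_id)
        if cur is None or aln.identity > cur[0]:
            best[aln.query_id] = (aln.identity, aln.coverage)
    calls = []
    for gene_id in cdnas_A:
        if gene_id in unplaced:
            calls.append(SpecificGeneCall(gene_id, "candidate"))
        else:
            ident, cov = best[gene_id]
            calls.append(SpecificGeneCall(gene_id, "placed", ident, cov))
    return calls


def exclude_syntenic(
    calls: list[SpecificGeneCall], syntenic_set: set[str]
) -> list[SpecificGeneCall]:
    """Step 2: demote candidates that are members of syntenic blocks."""
    return [
        replace(c, status="syntenic_excluded")
        if c.status == "candidate" and c.gene_id in syntenic_set
        else c
        for c in calls
    ]


def coverage_profiles(
    genome_A: GenomeAnnotation,
    depth: dict[str, np.ndarray],
    covered_site_min_depth: int = 1,
    gene_ids: list[str] | None = None,
) -> dict[str, CoverageProfile]:
    """Fraction of each gene's genomic span covered at the depth floor."""
    out = {}
    for g in genome_A.genes:
        if gene_ids is not None and g.gene_id not in gene_ids:
            continue
        d = depth.get(g.scaffold)
        if d is None or g.end > d.size:
            raise SpecificGeneError(f"gene {g.gene_id} outside mapped scaffold bounds")
        covered = int(np.count_nonzero(d[g.start : g.end] >= covered_site_min_depth))
        out[g.gene_id] = CoverageProfile(g.gene_id, g.length, covered)
    return out


def coverage_confirm(
    calls: list[SpecificGeneCall],
    reads_B: list[Read] | PlacementSet,
    genome_A: GenomeAnnotation,
    covered_site_min_depth: int = 1,
    max_covered_fraction: float = 0.50,
    max_substitutions: int = 2,
) -> list[SpecificGeneCall]:
    """Step 3: confirm candidates poorly covered by the other genotype's reads.

    A candidate becomes ``high_confidence_specific`` iff the fraction of
    its gene body covered (depth >= ``covered_site_min_depth``) by reads of
    the OTHER genotype is strictly below ``max_covered_fraction``.
    ``reads_B`` may be raw reads (mapped here) or an existing PlacementSet.
    """
    if isinstance(reads_B, PlacementSet):
        placements = reads_B
    else:
        placements = map_reads(reads_B, genome_A, max_substitutions=max_substitutions)
    depth = depth_profile(placements)
    candidate_ids = [c.gene_id for c in calls if c.status == "candidate"]
    profiles = coverage_profiles(genome_A, depth, covered_site_min_depth, candidate_ids)
    out = []
    for c in calls:
        if c.status != "candidate":
            out.append(c)
            continue
        frac = profiles[c.gene_id].covered_fraction
        status = "high_confidence_specific" if frac < max_covered_fraction else "candidate"
        out.append(replace(c, status=status, covered_fraction=frac))
    return out


def specific_gene_ids(calls: list[SpecificGeneCall]) -> set[str]:
    return {c.gene_id for c in calls if c.status == "high_confidence_specific"}
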