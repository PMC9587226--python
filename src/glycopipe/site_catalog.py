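"""Aggregate glycoPSMs into a non-redundant catalog of protein O-glycosites.

Site localization rests on ETD spectra only: a peptide-relative position whose
localization probability exceeds the cutoff (default 95%) becomes an
unambiguous protein-coordinate site; glycans that cannot be placed contribute
an ambiguous site spanning the peptide's S/T/Y stretch. Reporter-ion
quantification is taken from the HCD spectrum paired (same precursor) to the
highest-scoring ETD PSM of each glycopeptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .models import (
    GLYCO_RESIDUES,
    GlycoPSM,
    GlycoSite,
    ProteinRecord,
    ValidationError,
)


def _sty_span(psm: GlycoPSM) -> tuple[int, int]:
    """Protein-coordinate span of the peptide's S/T/Y residues."""
    positions = [
        psm.pep_start + i for i, aa in enumerate(psm.peptide) if aa in GLYCO_RESIDUES
    ]
    if not positions:
        raise ValidationError(
            f"{psm.accession} {psm.peptide}: glycoPSM on a peptide without S/T/Y"
        )
    return (min(positions), max(positions))


def build_catalog(
    psms: Iterable[GlycoPSM],
    proteome: Iterable[ProteinRecord],
    prob_cutoff: float = 95.0,
) -> list[GlycoSite]:
    """Build the non-redundant glycosite catalog.

    Parameters
    ----------
    psms:
        All glycoPSMs; only ETD PSMs contribute localization evidence.
    proteome:
        Protein records; every PSM accession must resolve and every mapped
        coordinate must hit an S, T or Y.
    prob_cutoff:
        Localization probability (percent) a position must *exceed* to be
        placed unambiguously.

    Returns
    -------
    Sites sorted by (accession, position); duplicates merged with summed PSM
    support and the best-scoring PSM retained.
    """
    sequences = {p.accession: p.sequence for p in proteome}
    merged: dict[tuple, GlycoSite] = {}

    for psm in psms:
        if psm.frag_type != "ETD":
            continue
        if psm.accession not in sequences:
            raise ValidationError(f"PSM references unknown accession {psm.accession!r}")
        seq = sequences[psm.accession]
        if psm.pep_end > len(seq):
            raise ValidationError(
                f"{psm.accession}: peptide {psm.pep_start}-{psm.pep_end} exceeds "
                f"protein length {len(seq)}"
            )
        localized = 0
        for pos, prob in zip(psm.site_positions, psm.site_probabilities):
            if prob <= prob_cutoff:
                continue
            localized += 1
            protein_pos = psm.pep_start + pos - 1
            residue = seq[protein_pos - 1]
            if residue not in GLYCO_RESIDUES:
                raise ValidationError(
                    f"{psm.accession} position {protein_pos}: residue {residue!r} "
                    f"is not S/T/Y (PSM {psm.peptide})"
                )
            key = ("unambiguous", psm.accession, protein_pos)
            _merge(merged, key, GlycoSite(
                accession=psm.accession,
                position=protein_pos,
                residue=residue,
                status="unambiguous",
                n_psms=1,
                best_psm=psm,
            ))
        # glycans without a confident position -> one ambiguous site each
        unplaced = psm.hexnac_count - localized
        if unplaced > 0:
            span = _sty_span(psm)
            for _ in range(unplaced):
                key = ("ambiguous", psm.accession, span)
                _merge(merged, key, GlycoSite(
                    accession=psm.accession,
                    position=span[0],
                    residue=seq[span[0] - 1],
                    status="ambiguous",
                    ambiguity_range=span,
                    n_psms=1,
                    best_psm=psm,
                ))

    return sorted(merged.values(), key=lambda s: (s.accession, s.position, s.status))


def _merge(merged: dict, key: tuple, site: GlycoSite) -> None:
    existing = merged.get(key)
    if existing is None:
        merged[key] = site
        return
    existing.n_psms += site.n_psms
    if site.best_psm is not None and (
        existing.best_psm is None
        or site.best_psm.psm_score > existing.best_psm.psm_score
    ):
        existing.best_psm = site.best_psm


@dataclass
class QuantSelection:
    """Outcome of quantification-spectrum selection for one glycopeptide."""

    psm: Optional[GlycoPSM]
    excluded: bool
    reason: str = ""


def select_quant_psm(psms: list[GlycoPSM]) -> QuantSelection:
    """Pick the intensity record for one glycopeptide.

    The ETD PSM with maximal ``psm_score`` (ties: first in input order)
    anchors the choice; the HCD PSM sharing its precursor supplies the
    reporter intensities. Without any ETD PSM the glycopeptide is excluded
    from quantification (signaled, not fatal).
    """
    etd = [p for p in psms if p.frag_type == "ETD"]
    if not etd:
        return QuantSelection(psm=None, excluded=True, reason="no ETD PSM")
    best = max(etd, key=lambda p: p.psm_score)  # max() keeps the first maximum
    if best.precursor_id:
        for p in psms:
            if p.frag_type == "HCD" and p.precursor_id == best.precursor_id:
                return QuantSelection(psm=p, excluded=False)
    return QuantSelection(psm=best, excluded=False)


def group_glycopeptides(psms: Iterable[GlycoPSM]) -> dict[tuple, list[GlycoPSM]]:
    """Group PSMs by glycopeptide identity (accession, coordinates, sequence),
    preserving input order within each group."""
    groups: dict[tuple, list[GlycoPSM]] = {}
    for psm in psms:
        groups.setdefault(psm.glycopeptide_key, []).append(psm)
    return groups


def single_site_filter(
    psms: Iterable[GlycoPSM],
) -> tuple[dict[tuple, list[GlycoPSM]], dict[tuple, list[GlycoPSM]]]:
    """Split glycopeptides into single-site and multi-site sets.

    A glycopeptide is single-site only when *every* supporting PSM carries
    exactly one HexNAc; mixed evidence (the same peptide seen with one and
    with several glycans) is conservatively routed to the multi-site,
    peptide-level table, since attribution of reporter signal to one site is
    then unsafe.
    """
    single: dict[tuple, list[GlycoPSM]] = {}
    multi: dict[tuple, list[GlycoPSM]] = {}
    for key, group in group_glycopeptides(psms).items():
        if all(p.hexnac_count == 1 for p in group):
            single[key] = group
        else:
            multi[key] = group
    return single, multi


@dataclass
class OverlapReport:
    """Protein- and site-level overlap of catalog a relative to catalog b."""

    n_proteins_a: int
    n_proteins_b: int
    n_proteins_shared: int
    protein_overlap_pct: float
    n_sites_a: int
    n_sites_b: int
    n_sites_shared: int
    site_overlap_pct: float
    sites_unique_a: int
    sites_unique_b: int


def compare_catalogs(a: list[GlycoSite], b: list[GlycoSite]) -> OverlapReport:
    """Overlap of two catalogs over the same proteome.

    Percentages are relative to catalog ``b`` (the reference): a site overlap
    of 77% means 77% of b's unambiguous sites are also in a.
    """
    sites_a = {s.key for s in a if s.status == "unambiguous"}
    sites_b = {s.key for s in b if s.status == "unambiguous"}
    prot_a = {acc for acc, _ in sites_a} | {s.accession for s in a}
    prot_b = {acc for acc, _ in sites_b} | {s.accession for s in b}
    shared_sites = sites_a & sites_b
    shared_prot = prot_a & prot_b
    return OverlapReport(
        n_proteins_a=len(prot_a),
        n_proteins_b=len(prot_b),
        n_proteins_shared=len(shared_prot),
        protein_overlap_pct=100.0 * len(shared_prot) / len(prot_b) if prot_b else 0.0,
        n_sites_a=len(sites_a),
        n_sites_b=len(sites_b),
        n_sites_shared=len(shared_sites),
        site_overlap_pct=100.0 * len(shared_sites) / len(sites_b) if sites_b else 0.0,
        sites_unique_a=len(sites_a - sites_b),
        sites_unique_b=len(sites_b - sites_a),
    )
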