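"""Assign glycosites to protein-region categories and summarise domain usage.

Five categories are recognised: annotated structural domains; stem regions
(the juxtamembrane extracellular stretch, within ``stem_window`` residues of
the transmembrane span, of type-I/II membrane proteins); functional regions;
protein termini (within ``terminus_window`` residues of the mature N-terminus
after signal-peptide cleavage, or of the C-terminus); and linkers (gaps of
less than ``linker_max`` residues between consecutive domains). A site
matching several predicates is resolved by a fixed precedence order — domain
membership is the most specific structural claim, so it wins by default.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Optional, Sequence

from .models import (
    DomainStats,
    FeatureAnnotation,
    GlycoSite,
    ProteinRecord,
    RegionAssignment,
    ValidationError,
)

DEFAULT_PRECEDENCE = ("domain", "stem", "functional_region", "terminus", "linker")


def percent_of(count: int, total: int) -> float:
    """Percentage with half-up rounding to one decimal (report convention)."""
    if total == 0:
        return 0.0
    return math.floor(count / total * 1000 + 0.5) / 10


def _check_features(
    protein: ProteinRecord, features: Sequence[FeatureAnnotation]
) -> None:
    for f in features:
        if f.accession != protein.accession:
            raise ValidationError(
                f"feature for {f.accession} passed with protein {protein.accession}"
            )
        if f.end > len(protein):
            raise ValidationError(
                f"{protein.accession}: feature {f.kind} {f.start}-{f.end} outside "
                f"protein of length {len(protein)}"
            )


def _domain_hit(
    pos: int, features: Sequence[FeatureAnnotation]
) -> Optional[FeatureAnnotation]:
    for f in features:
        if f.kind == "domain" and f.contains(pos):
            return f
    return None


def _stem_hit(
    pos: int,
    protein: ProteinRecord,
    features: Sequence[FeatureAnnotation],
    stem_window: int,
) -> Optional[tuple[FeatureAnnotation, int]]:
    if protein.topology not in ("type_I", "type_II"):
        return None
    for f in features:
        if f.kind != "transmembrane":
            continue
        # extracellular side: N-terminal for type I, C-terminal for type II
        if protein.topology == "type_I" and pos < f.start:
            distance = f.start - pos
        elif protein.topology == "type_II" and pos > f.end:
            distance = pos - f.end
        else:
            continue
        if distance <= stem_window:
            return f, distance
    return None


def _functional_hit(
    pos: int, features: Sequence[FeatureAnnotation]
) -> Optional[FeatureAnnotation]:
    for f in features:
        if f.kind == "functional_region" and f.contains(pos):
            return f
    return None


def _terminus_hit(
    pos: int,
    protein: ProteinRecord,
    features: Sequence[FeatureAnnotation],
    terminus_window: int,
) -> bool:
    mature_start = 1
    for f in features:
        if f.kind == "signal_peptide":
            mature_start = max(mature_start, f.end + 1)
    n_offset = pos - mature_start + 1  # residue index counted from mature N-term
    c_offset = len(protein) - pos + 1
    return (1 <= n_offset <= terminus_window) or (1 <= c_offset <= terminus_window)


def _linker_hit(
    pos: int, features: Sequence[FeatureAnnotation], linker_max: int
) -> bool:
    domains = sorted(
        (f for f in features if f.kind == "domain"), key=lambda f: (f.start, f.end)
    )
    for prev, nxt in zip(domains, domains[1:]):
        gap = nxt.start - prev.end - 1
        if gap < linker_max and prev.end < pos < nxt.start:
            return True
    return False


def classify_site(
    site: GlycoSite,
    protein: ProteinRecord,
    features: Sequence[FeatureAnnotation],
    stem_window: int = 50,
    linker_max: int = 100,
    terminus_window: int = 10,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> RegionAssignment:
    """Place one unambiguous site into a region category (or "unassigned")."""
    if site.status != "unambiguous":
        raise ValidationError("only unambiguous sites can be region-classified")
    _check_features(protein, features)
    pos = site.position

    for category in precedence:
        if category == "domain":
            hit = _domain_hit(pos, features)
            if hit is not None:
                return RegionAssignment(site, "domain", feature=hit)
        elif category == "stem":
            stem = _stem_hit(pos, protein, features, stem_window)
            if stem is not None:
                return RegionAssignment(site, "stem", feature=stem[0],
                                        distance=stem[1])
        elif category == "functional_region":
            hit = _functional_hit(pos, features)
            if hit is not None:
                return RegionAssignment(site, "functional_region", feature=hit)
        elif category == "terminus":
            if _terminus_hit(pos, protein, features, terminus_window):
                return RegionAssignment(site, "terminus")
        elif category == "linker":
            if _linker_hit(pos, features, linker_max):
                return RegionAssignment(site, "linker")
        else:
            raise ValidationError(f"unknown category in precedence: {category!r}")
    return RegionAssignment(site, "unassigned")


def summarize_regions(
    assignments: Iterable[RegionAssignment],
) -> dict[str, tuple[int, float]]:
    """Per-category site counts and percentages of the total catalog.

    Percentages use one-decimal half-up rounding, matching report style.
    """
    counts = Counter(a.category for a in assignments)
    total = sum(counts.values())
    categories = ("domain", "stem", "linker", "terminus", "functional_region",
                  "unassigned")
    return {
        cat: (counts.get(cat, 0), percent_of(counts.get(cat, 0), total))
        for cat in categories
    }


def relative_position_bin(pos: int, start: int, end: int, n_bins: int = 10) -> int:
    """Decile (1..n_bins) of a site within a domain, midpoint-offset rule.

    The relative position (pos - start + 0.5) / length puts the first and last
    residues symmetrically into bins 1 and n_bins.
    """
    length = end - start + 1
    if length <= 0:
        raise ValidationError(f"zero-length domain {start}-{end}")
    rel = (pos - start + 0.5) / length
    return min(n_bins, int(rel * n_bins) + 1)


def domain_statistics(
    catalog: Sequence[GlycoSite],
    proteome: Sequence[ProteinRecord],
    features: Sequence[FeatureAnnotation],
    n_bins: int = 10,
) -> list[DomainStats]:
    """Per-domain-type glycosylation rate and positional distribution.

    Domain instances are counted over catalog glycoproteins only (a protein
    contributes one instance per copy of the domain it carries). Only
    unambiguous sites count as occupancy evidence.
    """
    glycoproteins = {s.accession for s in catalog}
    sites_by_protein: dict[str, list[int]] = {}
    for s in catalog:
        if s.status == "unambiguous":
            sites_by_protein.setdefault(s.accession, []).append(s.position)

    per_label: dict[str, dict] = {}
    for f in features:
        if f.kind != "domain" or f.accession not in glycoproteins:
            continue
        if f.length <= 0:
            raise ValidationError(f"zero-length domain {f.accession} {f.label}")
        entry = per_label.setdefault(
            f.label, {"total": 0, "occupied": 0, "sites_per": [], "bins": [0] * n_bins}
        )
        entry["total"] += 1
        in_domain = [p for p in sites_by_protein.get(f.accession, ())
                     if f.contains(p)]
        if in_domain:
            entry["occupied"] += 1
            entry["sites_per"].append(len(in_domain))
            for p in in_domain:
                entry["bins"][relative_position_bin(p, f.start, f.end, n_bins) - 1] += 1

    stats = [
        DomainStats(
            domain_label=label,
            n_domains_total=e["total"],
            n_domains_glycosylated=e["occupied"],
            rate=e["occupied"] / e["total"],
            sites_per_domain=e["sites_per"],
            position_bins=e["bins"],
        )
        for label, e in per_label.items()
    ]
    stats.sort(key=lambda d: (-sum(d.sites_per_domain), d.domain_label))
    return stats
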