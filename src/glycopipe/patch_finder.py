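"""Detect and rank high-density O-glycan patches (mucin-like regions).

A patch is a maximal cluster of glycosites satisfying the density rule:
at least ``min_sites`` sites within some window of ``window`` consecutive
residues (defaults 5 within 25). Qualifying windows that share a member site
are merged into one maximal patch, so a dense cluster is reported once rather
than as many shifted windows.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .models import ConfigurationError, GlycoSite, Patch


def find_patches(
    positions: Iterable[int],
    accession: str = "",
    window: int = 25,
    min_sites: int = 5,
) -> list[Patch]:
    """Find glycan patches among the site positions of one protein.

    Parameters
    ----------
    positions:
        Protein-coordinate site positions (unambiguous sites); duplicates are
        collapsed and unsorted input is sorted internally.
    window, min_sites:
        Density rule: a window of ``window`` consecutive residues must contain
        ``min_sites`` or more sites.

    Notes
    -----
    Only windows whose left edge sits on a site need be examined: any
    qualifying window can be slid right until its left edge hits its first
    member without losing members on the right.
    """
    if window < 1:
        raise ConfigurationError(f"window must be >= 1, got {window}")
    if min_sites < 1:
        raise ConfigurationError(f"min_sites must be >= 1, got {min_sites}")
    pos = sorted(set(positions))
    if not pos:
        return []

    qualifying: list[list[int]] = []
    j = 0
    for i, left in enumerate(pos):
        right = left + window - 1
        j = max(j, i)
        while j < len(pos) and pos[j] <= right:
            j += 1
        members = pos[i:j]
        if len(members) >= min_sites:
            qualifying.append(members)

    # merge windows sharing >=1 member; windows are sorted by left edge so
    # any transitive overlap is also an adjacent overlap
    patches: list[Patch] = []
    current: list[int] = []
    for members in qualifying:
        if current and members[0] <= current[-1]:
            for p in members:
                if p > current[-1]:
                    current.append(p)
        else:
            if current:
                patches.append(_make_patch(accession, current))
            current = list(members)
    if current:
        patches.append(_make_patch(accession, current))
    return patches


def _make_patch(accession: str, members: list[int]) -> Patch:
    start, end = members[0], members[-1]
    return Patch(
        accession=accession,
        start=start,
        end=end,
        n_sites=len(members),
        member_sites=list(members),
        density=len(members) / (end - start + 1),
    )


def find_patches_catalog(
    catalog: Sequence[GlycoSite],
    window: int = 25,
    min_sites: int = 5,
    include_ambiguous: bool = False,
) -> list[Patch]:
    """Run the patch finder over a whole site catalog, per protein.

    Ambiguous sites are excluded by default since their coordinates are
    ranges; ``include_ambiguous`` admits them at their nominal position.
    """
    by_protein: dict[str, list[int]] = {}
    for s in catalog:
        if s.status == "unambiguous" or include_ambiguous:
            by_protein.setdefault(s.accession, []).append(s.position)
    patches: list[Patch] = []
    for accession in sorted(by_protein):
        patches.extend(
            find_patches(by_protein[accession], accession, window, min_sites)
        )
    return patches


def rank_patches(patches: Iterable[Patch], report_min: int = 0) -> list[Patch]:
    """Order patches by size descending, ties by span ascending then accession.

    ``report_min`` drops patches with fewer member sites (e.g. 7 for a
    large-patch report).
    """
    kept = [p for p in patches if p.n_sites >= report_min]
    return sorted(
        kept,
        key=lambda p: (-p.n_sites, p.end - p.start + 1, p.accession, p.start),
    )
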