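"""Region classification rules, precedence, and domain statistics."""

from __future__ import annotations

import numpy as np
import pytest

from glycopipe.models import (
    FeatureAnnotation,
    GlycoSite,
    ProteinRecord,
    ValidationError,
)
from glycopipe.region_mapper import (
    DEFAULT_PRECEDENCE,
    classify_site,
    domain_statistics,
    percent_of,
    relative_position_bin,
    summarize_regions,
)


def site(acc: str, pos: int, residue: str = "S") -> GlycoSite:
    return GlycoSite(acc, pos, residue, "unambiguous")


class TestClassifySite:
    def test_stem_site_on_type1_protein(self, type1_protein):
        protein, features = type1_protein
        # TM 401-421; site 370 is 31 residues N-terminal of the TM start
        assignment = classify_site(site("M1", 370), protein, features)
        assert assignment.category == "stem"
        assert assignment.distance == 31

    def test_terminus_after_signal_peptide_cleavage(self, type1_protein):
        protein, features = type1_protein
        # mature N-terminus at 21; residue 25 is the 5th mature residue
        assignment = classify_site(site("M1", 25), protein, features)
        assert assignment.category == "terminus"

    def test_gap_of_119_is_not_a_linker(self):
        protein = ProteinRecord("P1", "ST" * 250)
        features = [
            FeatureAnnotation("P1", "domain", 100, 200, "Cadherin"),
            FeatureAnnotation("P1", "domain", 320, 400, "Cadherin"),
        ]
        assert classify_site(site("P1", 260), protein, features).category == \
            "unassigned"

    def test_gap_of_49_is_a_linker(self):
        protein = ProteinRecord("P1", "ST" * 200)
        features = [
            FeatureAnnotation("P1", "domain", 100, 200, "Cadherin"),
            FeatureAnnotation("P1", "domain", 250, 320, "Cadherin"),
        ]
        assert classify_site(site("P1", 225), protein, features).category == \
            "linker"

    def test_domain_wins_over_stem(self, type1_protein):
        protein, features = type1_protein
        features = features + [
            FeatureAnnotation("M1", "domain", 350, 380, "Cadherin")
        ]
        assignment = classify_site(site("M1", 370), protein, features)
        assert assignment.category == "domain"
        assert assignment.feature.label == "Cadherin"

    def test_type2_stem_is_c_terminal_of_tm(self):
        protein = ProteinRecord("P2", "ST" * 250, topology="type_II")
        features = [FeatureAnnotation("P2", "transmembrane", 30, 50)]
        assignment = classify_site(site("P2", 80), protein, features)
        assert assignment.category == "stem"
        assert assignment.distance == 30
        # N-terminal side is cytosolic for type II: not a stem
        # (position 10 is, however, within the N-terminal terminus window)
        assert classify_site(site("P2", 25), protein, features).category != "stem"

    def test_secreted_protein_has_no_stem(self):
        protein = ProteinRecord("P3", "ST" * 250, topology="secreted")
        features = [FeatureAnnotation("P3", "transmembrane", 401, 421)]
        assert classify_site(site("P3", 370), protein, features).category != "stem"

    def test_feature_outside_protein_rejected(self):
        protein = ProteinRecord("P1", "ST" * 10)
        features = [FeatureAnnotation("P1", "domain", 10, 500, "X")]
        with pytest.raises(ValidationError, match="outside"):
            classify_site(site("P1", 5), protein, features)

    def test_ambiguous_site_rejected(self):
        protein = ProteinRecord("P1", "ST" * 10)
        ambiguous = GlycoSite("P1", 3, "T", "ambiguous", ambiguity_range=(3, 9))
        with pytest.raises(ValidationError, match="unambiguous"):
            classify_site(ambiguous, protein, [])


def _oracle_classify(pos, protein, features, stem_window=50, linker_max=100,
                     terminus_window=10):
    """Independent re-statement of every predicate plus the precedence table."""
    cats = set()
    doms = sorted([f for f in features if f.kind == "domain"],
                  key=lambda f: (f.start, f.end))
    if any(f.start <= pos <= f.end for f in doms):
        cats.add("domain")
    for f in features:
        if f.kind != "transmembrane":
            continue
        if protein.topology == "type_I" and 0 < f.start - pos <= stem_window:
            cats.add("stem")
        if protein.topology == "type_II" and 0 < pos - f.end <= stem_window:
            cats.add("stem")
    if any(f.kind == "functional_region" and f.start <= pos <= f.end
           for f in features):
        cats.add("functional_region")
    mature = 1 + max([f.end for f in features if f.kind == "signal_peptide"],
                     default=0)
    if mature <= pos <= mature + terminus_window - 1:
        cats.add("terminus")
    if len(protein) - terminus_window + 1 <= pos <= len(protein):
        cats.add("terminus")
    for a, b in zip(doms, doms[1:]):
        if b.start - a.end - 1 < linker_max and a.end < pos < b.start:
            cats.add("linker")
    for category in DEFAULT_PRECEDENCE:
        if category in cats:
            return category
    return "unassigned"


def test_classifier_matches_predicate_oracle_on_random_fixtures():
    rng = np.random.default_rng(7)
    for trial in range(150):
        length = int(rng.integers(120, 400))
        topology = ["type_I", "type_II", "secreted", "other"][
            int(rng.integers(0, 4))
        ]
        protein = ProteinRecord("P1", "ST" * (length // 2 + 1), topology=topology)
        protein = ProteinRecord("P1", protein.sequence[:length],
                                topology=topology)
        features = []
        if rng.random() < 0.5:
            features.append(FeatureAnnotation("P1", "signal_peptide", 1,
                                              int(rng.integers(15, 25))))
        if topology in ("type_I", "type_II") or rng.random() < 0.3:
            tm_start = int(rng.integers(30, length - 25))
            features.append(FeatureAnnotation("P1", "transmembrane", tm_start,
                                              tm_start + 20))
        for _ in range(int(rng.integers(0, 3))):
            a = int(rng.integers(1, length - 20))
            b = min(length, a + int(rng.integers(10, 80)))
            features.append(FeatureAnnotation("P1", "domain", a, b, "D"))
        if rng.random() < 0.4:
            a = int(rng.integers(1, length - 12))
            features.append(FeatureAnnotation("P1", "functional_region", a,
                                              a + 10))
        assert len(features) <= 5
        for pos in rng.integers(1, length + 1, size=15):
            pos = int(pos)
            got = classify_site(site("P1", pos), protein, features).category
            assert got == _oracle_classify(pos, protein, features), (
                trial, pos, topology, features
            )


def test_stem_window_monotonicity(type1_protein):
    protein, features = type1_protein
    positions = list(range(330, 401, 5))
    counts = []
    for window in (20, 35, 50, 80):
        n = sum(
            classify_site(site("M1", p), protein, features,
                          stem_window=window).category == "stem"
            for p in positions
        )
        counts.append(n)
    assert counts == sorted(counts)  # enlarging the window never loses stems


def test_linker_max_monotonicity():
    protein = ProteinRecord("P1", "ST" * 300)
    features = [
        FeatureAnnotation("P1", "domain", 50, 100, "D"),
        FeatureAnnotation("P1", "domain", 180, 220, "D"),
        FeatureAnnotation("P1", "domain", 300, 350, "D"),
    ]
    positions = list(range(101, 300, 7))
    counts = []
    for linker_max in (120, 90, 60, 30):
        n = sum(
            classify_site(site("P1", p), protein, features,
                          linker_max=linker_max).category == "linker"
            for p in positions
        )
        counts.append(n)
    assert counts == sorted(counts, reverse=True)


class TestSummaries:
    def test_every_site_gets_one_category_and_fractions_sum(self, small_sim):
        from glycopipe.site_catalog import build_catalog

        _, proteome, features, _, psms = small_sim
        catalog = [s for s in build_catalog(psms, proteome)
                   if s.status == "unambiguous"]
        proteins = {p.accession: p for p in proteome}
        by_protein: dict = {}
        for f in features:
            by_protein.setdefault(f.accession, []).append(f)
        assignments = [
            classify_site(s, proteins[s.accession],
                          by_protein.get(s.accession, []))
            for s in catalog
        ]
        assert len(assignments) == len(catalog)
        summary = summarize_regions(assignments)
        assert sum(c for c, _ in summary.values()) == len(catalog)
        assert sum(p for _, p in summary.values()) == pytest.approx(100.0,
                                                                    abs=0.3)

    def test_all_unassigned_gives_zero_percentages(self):
        protein = ProteinRecord("P1", "ST" * 300)
        assignments = [classify_site(site("P1", p), protein, [])
                       for p in (150, 200, 250)]
        summary = summarize_regions(assignments)
        for category, (count, pct) in summary.items():
            if category != "unassigned":
                assert count == 0 and pct == 0.0

    def test_percent_rounding_is_half_up(self):
        assert percent_of(1, 16) == 6.3  # 6.25 rounds up, not to even


class TestDomainStatistics:
    def _fixture(self):
        protein = ProteinRecord("P1", "ST" * 300)
        features = [
            FeatureAnnotation("P1", "domain", 1 + 100 * k, 100 * (k + 1),
                              "Cadherin")
            for k in range(4)
        ]
        catalog = [site("P1", 150), site("P1", 160), site("P1", 250)]
        return protein, features, catalog

    def test_rate_counts_occupied_instances(self):
        protein, features, catalog = self._fixture()
        stats = domain_statistics(catalog, [protein], features)
        assert len(stats) == 1
        d = stats[0]
        assert d.n_domains_total == 4
        assert d.n_domains_glycosylated == 2
        assert d.rate == pytest.approx(0.5)
        assert sorted(d.sites_per_domain) == [1, 2]
        assert sum(d.position_bins) == 3

    def test_domains_on_non_catalog_proteins_not_counted(self):
        protein, features, catalog = self._fixture()
        other = ProteinRecord("P2", "ST" * 300)
        extra = [FeatureAnnotation("P2", "domain", 1, 100, "Cadherin")]
        stats = domain_statistics(catalog, [protein, other], features + extra)
        assert stats[0].n_domains_total == 4  # P2 has no catalog sites

    def test_boundary_bins(self):
        assert relative_position_bin(100, 100, 199) == 1
        assert relative_position_bin(199, 100, 199) == 10
        assert relative_position_bin(150, 100, 199) == 6
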