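"""Shared fixtures: tiny hand-built records and small synthetic data sets."""

from __future__ import annotations

import pytest

from glycopipe.models import FeatureAnnotation, GlycoPSM, ProteinRecord
from glycopipe.simulate import (
    SimConfig,
    simulate_proteome,
    simulate_sites_and_psms,
)


def make_psm(
    peptide: str = "AASTPTKLTYSK",
    accession: str = "P1",
    pep_start: int = 100,
    hexnac: int = 1,
    positions: list[int] | None = None,
    probs: list[float] | None = None,
    frag: str = "ETD",
    score: float = 300.0,
    intensities: dict | None = None,
    precursor: str = "",
) -> GlycoPSM:
    return GlycoPSM(
        peptide=peptide,
        accession=accession,
        pep_start=pep_start,
        pep_end=pep_start + len(peptide) - 1,
        hexnac_count=hexnac,
        hex_count=0,
        site_positions=positions if positions is not None else [3],
        site_probabilities=probs if probs is not None else [99.2],
        frag_type=frag,
        psm_score=score,
        intensities=intensities or {},
        precursor_id=precursor,
    )


@pytest.fixture
def protein_p1() -> ProteinRecord:
    # 200 aa; peptide AASTPTKLTYSK occupies 100-111
    seq = list("A" * 200)
    seq[99:111] = "AASTPTKLTYSK"
    seq[150] = "S"
    return ProteinRecord("P1", "".join(seq))


@pytest.fixture
def type1_protein() -> tuple[ProteinRecord, list[FeatureAnnotation]]:
    """Type-I membrane protein, 500 aa, TM at 401-421, signal peptide 1-20."""
    protein = ProteinRecord("M1", "ST" * 250, topology="type_I")
    features = [
        FeatureAnnotation("M1", "signal_peptide", 1, 20),
        FeatureAnnotation("M1", "transmembrane", 401, 421),
    ]
    return protein, features


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic small simulation shared across read-only tests."""
    config = SimConfig(seed=11, n_proteins=30, n_sites=100,
                       frac_below_cutoff=0.0, decoy_fraction=0.1)
    proteome, features = simulate_proteome(config)
    truth, psms = simulate_sites_and_psms(config, proteome, features)
    return config, proteome, features, truth, psms
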