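"""Shared fixtures: synthetic panels and the designed multiplex, built once."""

from __future__ import annotations

import pytest

from probioplex import primers, scheme, synth


@pytest.fixture(scope="session")
def pgi_panel():
    """The 20-taxon discriminative-locus panel under study conditions."""
    return synth.generate_panel(synth.default_pgi_spec(seed=0))


@pytest.fixture(scope="session")
def panel_assays(pgi_panel):
    return primers.design_panel_assays(pgi_panel)


@pytest.fixture(scope="session")
def panel_scheme(panel_assays):
    return scheme.partition_assays(panel_assays, plex_size=5)


@pytest.fixture(scope="session")
def small_panel():
    """A 6-taxon panel for unit tests that redesign assays."""
    return synth.generate_panel(synth.default_pgi_spec(seed=0, n_taxa=6, gene_length=400))


@pytest.fixture(scope="session")
def s16_panel():
    """The conserved 16S-like panel."""
    return synth.generate_panel(synth.default_16s_spec(seed=0))


@pytest.fixture(scope="session")
def v4_refs(s16_panel):
    return synth.v4_references(s16_panel)
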