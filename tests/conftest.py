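"""Shared fixtures: synthetic datasets sized for the fidelity checks."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m5cdevmap import caller, synthetic

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
from m5cdevmap.models import SimulationConfig
from m5cdevmap.synthetic import LengthParams


@pytest.fixture
def small_transcriptome():
    """Fresh small transcriptome per test (plant_truth edits in place)."""
    def make(n_genes=20, seed=3, lengths=LengthParams(100, 500, 400)):
        return synthetic.make_transcriptome(n_genes, lengths, seed=seed)

    return make


class FidelityRun:
    """Two-replicate simulation at the study conditions plus call results."""

    def __init__(self):
        self.transcriptome = synthetic.make_transcriptome(
            200, LengthParams(150, 1500, 550), seed=3
        )
        self.truth = synthetic.plant_truth(
            self.transcriptome, 500, 0.25, (0.2, 0.8), seed=4
        )
        self.config = SimulationConfig(
            n_genes=200, coverage_mean=60.0, conversion_rate=0.995,
            bad_read_fraction=0.02, read_len=100, seed=11,
        )
        self.replicates = synthetic.simulate_replicates(
            self.transcriptome, self.truth, self.config
        )
        self.sites, self.audit = caller.call_sites(
            self.replicates, self.transcriptome
        )
        self.truth_keys = {(s.transcript_id, s.position) for s in self.truth}
        self.called_keys = {(s.transcript_id, s.position) for s in self.sites}

    def coverage_maps(self):
        maps = []
        for rep in self.replicates:
            pil = caller.pileup_from_reads(rep, 30)
            maps.append({k: v.coverage_hq for k, v in pil.items()})
        return maps


@pytest.fixture(scope="session")
def fidelity_run() -> FidelityRun:
    return FidelityRun()


@pytest.fixture(scope="session")
def species_pair_recovery():
    """Species pair with known logistic coefficients for recovery checks."""
    transcriptome = synthetic.make_transcriptome(
        250, LengthParams(150, 1500, 550), seed=21
    )
    truth = synthetic.plant_truth(
        transcriptome, 4000, 0.0, (0.2, 0.8), seed=22, min_spacing=60
    )
    coefs = {
        "intercept": -0.3, "pair+1": 2.0, "pair-1": 1.2,
        "pair+5": -1.5, "pair-10": 1.0, "pair+15": -0.8,
    }
    pair = synthetic.make_species_pair(
        transcriptome, truth, sub_rate=0.0, glm_coefs=coefs, seed=23
    )
    return pair, coefs
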