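"""Shared fixtures: tiny trees, rule files, and a reusable synthetic bundle."""

import numpy as np
import pytest

from stramtf.phylo import parse_newick
from stramtf.simulate import SimConfig, simulate_bundle


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):0.5,C:2);")


@pytest.fixture
def six_tip_tree():
    return parse_newick("(((A:1,B:2):1,(C:1,D:1):2):1,(E:3,F:1):2);")


@pytest.fixture
def rule_file(tmp_path):
    """Rule TSV exercising OR-clauses, pure-AND rows and forbidden domains."""
    text = "\n".join(
        [
            "family_id\tcategory\tdomain_id\ttype\tclause_id\tga_cutoff",
            "C2H2\tTF\tzf-C2H2\tshould\tc1\t25.0",
            "MYB\tTF\tMyb_DNA-binding\tshould\tc1\t22.0",
            "MYB\tTF\tSANT\tshould\tc1\t21.0",
            "MYB\tTF\tResponse_reg\tshould_not\t\t20.0",
            "HSF\tTF\tHSF_DNA-bind\tshould\tc1\t24.0",
            "HSF\tTF\tVert_HS_TF\tshould\tc2\t18.0",
            "GNAT\tTR\tAcetyltransf_1\tshould\tc1\t23.0",
        ]
    )
    path = tmp_path / "rules.tsv"
    path.write_text(text + "\n", encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def small_bundle():
    """A compact study: 8 species, 12 families, planted truths of each kind."""
    cfg = SimConfig(
        n_tips=8,
        n_families=12,
        seed=11,
        planted_correlations=(("C2H2", "predicted_proteins", 0.9),),
        decoy_fraction=0.2,
        noise_hits_per_species=10,
    )
    return simulate_bundle(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
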