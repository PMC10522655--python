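import pandas as pd
import pytest


def make_chain(chain_type="beta", v="TRBV19", j="TRBJ2-7", cdr3="CASSIRSSYEQYF",
               umi=4, productive=True, full_length=True):
    return {"chain_type": chain_type, "v_gene": v, "j_gene": j, "cdr3_aa": cdr3,
            "umi": umi, "productive": productive, "full_length": full_length}


def make_capture(feature_id="pMHC_000", umi=6, allele="A*02:01",
                 peptide="GILGFVFTL", neg=False):
    return {"feature_id": feature_id, "peptide": peptide, "hla_allele": allele,
            "umi": umi, "is_negative_control": neg}


_CORE = "AAACCTGTCTAACTTC"


def make_gem(i=0, donor="d1", chains=None, captures=None, is_cell=True, core=None):
    if core is None:
        # vary the core deterministically per index
        alphabet = "ACGT"
        core = "".join(alphabet[(i >> (2 * k)) % 4] for k in range(16))
    return {"barcode_full": f"{core}-1-{donor}", "barcode_core": core,
            "donor": donor, "is_cell": is_cell,
            "chains": chains if chains is not None else [make_chain()],
            "captures": captures if captures is not None else [make_capture()]}


def gem_frame(rows):
    return pd.DataFrame(rows, columns=["barcode_full", "barcode_core", "donor",
                                       "is_cell", "chains", "captures"])


@pytest.fixture
def gem_builder():
    return make_gem


@pytest.fixture(scope="session")
def sim_small():
    """A small noisy simulated dataset shared across tests."""
    from itrap import SimConfig, simulate_dataset
    return simulate_dataset(SimConfig(n_clonotypes=120, seed=11))
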