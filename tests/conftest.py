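import numpy as np
import pytest

from fragbb.synthdata import SyntheticSpec, generate_dataset

# a diverse drug-like fixture set used across structure/round-trip tests
DRUGLIKE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",   # caffeine
    "CC(N)Cc1ccccc1",                 # amphetamine
    "c1ccc2c(c1)cccc2",               # naphthalene
    "OCC(O)CO",                       # glycerol
    "ClC(Cl)(Cl)Cl",                  # carbon tetrachloride
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",     # procainamide
    "CN(C)CCOC(c1ccccc1)c1ccccc1",    # diphenhydramine
    "NC(=O)c1ccncc1",                 # isonicotinamide
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "OC(=O)c1ccccc1O",                # salicylic acid
    "C1CCNCC1",                       # piperidine
    "c1ccsc1",                        # thiophene
    "CC(C)NCC(O)COc1ccccc1",          # propranolol-like ether
    "FC(F)(F)c1ccccc1",               # benzotrifluoride
    "CCOC(=O)C",                      # ethyl acetate
    "NCCc1ccc(O)c(O)c1",              # dopamine
    "CSCC(N)C(=O)O",                  # methionine-like
    "O=S(=O)(N)c1ccccc1",             # benzenesulfonamide
    "CC1=CC(=O)CC(C)(C)C1",          # isophorone
    "Clc1ccc(cc1)C(c1ccccc1)N1CCCC1", # aryl amine
]


@pytest.fixture(scope="session")
def small_synth():
    """A small noiseless-ish synthetic dataset shared by fast tests."""
    records, coefs = generate_dataset(
        SyntheticSpec(n_compounds=60, noise_sd=0.05, seed=7)
    )
    return records, coefs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
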