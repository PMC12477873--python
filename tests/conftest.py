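import numpy as np
import pandas as pd
import pytest

from microwbm.model import Reaction, Reconstruction


@pytest.fixture
def chain_model() -> Reconstruction:
    """Linear chain diet -> lumen -> blood with a 5 mmol/day uptake bottleneck.

    The maximal demand flux for met A in blood is exactly 5.
    """
    m = Reconstruction(id="chain")
    m.add_reaction(Reaction("Diet_EX_A[d]", {"A[d]": -1.0}, -5.0, 1e6))
    m.add_reaction(Reaction("T_diet_A", {"A[d]": -1.0, "A[luLI]": 1.0}, 0.0, 1e6))
    m.add_reaction(Reaction("T_abs_A", {"A[luLI]": -1.0, "A[bc]": 1.0}, 0.0, 1e6))
    m.add_reaction(Reaction("T_u_A", {"A[bc]": -1.0, "A[u]": 1.0}, 0.0, 1e6))
    m.add_reaction(Reaction("EX_A[u]", {"A[u]": -1.0}, 0.0, 1e6))
    return m


def two_species_community(r_a: float = 0.6, r_b: float = 0.4,
                          cap_a: float = 1e6, cap_b: float = 1e6):
    """Hand-built joined-style model with two coupled species producing P.

    Species A is the sole producer of P; species B produces Q. Both biomass
    fluxes are pinned to their abundances through the community-biomass
    excretion at [1, 1]. Diet supplies the precursor N generously.
    """
    m = Reconstruction(id="two_species")
    m.add_reaction(Reaction("Diet_EX_N[d]", {"N[d]": -1.0}, -1000.0, 1e6))
    m.add_reaction(Reaction("T_diet_N", {"N[d]": -1.0, "N[luM]": 1.0}, 0.0, 1e6))
    for sp, prod, cap in (("A", "P", cap_a), ("B", "Q", cap_b)):
        m.add_reaction(Reaction(f"{sp}__upt_N",
                                {"N[luM]": -1.0, f"{sp}__N[c]": 1.0},
                                0.0, cap, species=sp))
        m.add_reaction(Reaction(f"{sp}__conv",
                                {f"{sp}__N[c]": -1.0, f"{sp}__{prod}[c]": 1.0},
                                0.0, 1e6, species=sp))
        m.add_reaction(Reaction(f"{sp}__sec",
                                {f"{sp}__{prod}[c]": -1.0, f"{prod}[luM]": 1.0},
                                0.0, 1e6, species=sp))
        m.add_reaction(Reaction(f"pan{sp}_biomass",
                                {f"{sp}__N[c]": -1.0, f"pan{sp}_biomass[c]": 1.0},
                                0.0, 1e6, species=sp, is_biomass=True))
        m.add_reaction(Reaction(f"T_abs_{prod}",
                                {f"{prod}[luM]": -1.0, f"{prod}[bc]": 1.0},
                                0.0, 1e6))
    m.add_reaction(Reaction(
        "communityBiomass",
        {"panA_biomass[c]": -r_a, "panB_biomass[c]": -r_b,
         "microbiota_LI_biomass[luM]": 1.0}, 0.0, 1e6))
    m.add_reaction(Reaction(
        "Excretion_EX_microbiota_LI_biomass[fe]",
        {"microbiota_LI_biomass[luM]": -1.0}, 1.0, 1.0))
    m.couplings = [
        {"rxn": rid, "biomass_rxn": f"pan{sp}_biomass", "factor": 400.0}
        for sp in ("A", "B")
        for rid in (f"{sp}__upt_N", f"{sp}__conv", f"{sp}__sec")
    ]
    from microwbm.community import HostMicrobiomeModel

    out = HostMicrobiomeModel(id=m.id, metabolites=m.metabolites,
                              reactions=m.reactions, couplings=m.couplings,
                              abundances={"A": r_a, "B": r_b})
    return out


@pytest.fixture
def two_species_model():
    return two_species_community()


@pytest.fixture
def metadata_frame():
    """Small synthetic metadata table with the full covariate set."""
    rng = np.random.default_rng(42)
    n = 60
    idx = [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame({
        "diagnosis": np.where(np.arange(n) < n // 2, "PD", "control"),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "age": rng.normal(66, 8, n).round(1),
        "bmi": rng.normal(28, 5, n).round(1),
        "alcohol": rng.integers(0, 2, n),
        "laxatives": rng.integers(0, 2, n),
        "pain_meds": rng.integers(0, 2, n),
        "mood_meds": rng.integers(0, 2, n),
        "antihistamines": rng.integers(0, 2, n),
        "sleep_aid": rng.integers(0, 2, n),
        "read_count": rng.integers(5_000_000, 30_000_000, n),
    }, index=idx)
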