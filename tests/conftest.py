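import pytest

from plcgamma.analysis import standard_variants, variant_scan
from plcgamma.ode import make_network
from plcgamma.params import ParameterSet
from plcgamma.rules import build_plcg_ruleset


@pytest.fixture(scope="session")
def base_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def ruleset():
    return build_plcg_ruleset()


@pytest.fixture(scope="session")
def base_network(base_params):
    return make_network(base_params)


@pytest.fixture(scope="session")
def kc_ka_variants():
    """The six 10-fold autoinhibition / membrane-affinity variants."""
    return [v for v in standard_variants() if v.kind in ("Kc", "Ka")]


@pytest.fixture(scope="session")
def scan_kp100(base_params, kc_ka_variants):
    """Variant panel (activation + decay) at the base K_p = 100, one dose."""
    return variant_scan(base_params, kc_ka_variants, rtk_total=0.05)


@pytest.fixture(scope="session")
def scan_kp10(base_params, kc_ka_variants):
    """Variant panel at K_p = 10 (reduced cSH2-pTyr783 on-rate), activation only."""
    p = base_params.with_edits(k_bind_p=10.0)
    return variant_scan(p, kc_ka_variants, rtk_total=0.05, decay=False)
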