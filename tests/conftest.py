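import numpy as np
import pytest

from medperm import CorrelationCondition, MediationData


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def random_data(rng):
    """Unstructured continuous data with one covariate, n = 40."""
    n = 40
    return MediationData(
        x=rng.standard_normal(n),
        m=rng.standard_normal(n),
        y=rng.standard_normal(n),
        c=rng.standard_normal((n, 1)),
    )


@pytest.fixture
def chain_data(rng):
    """Strong mediated chain: m tracks x, y tracks m, modest noise."""
    n = 30
    x = rng.standard_normal(n)
    m = x + 0.3 * rng.standard_normal(n)
    y = m + 0.3 * rng.standard_normal(n)
    c = rng.standard_normal((n, 1))
    return MediationData(x=x, m=m, y=y, c=c)


def condition_table1(row: int) -> CorrelationCondition:
    """Scenario-b null conditions by published row number (1-16).

    Rows 1-8 are n=30 and 9-16 the same structures at n=100, so only the
    correlation structure of rows 1-8 is needed.
    """
    structures = {
        1: dict(s=0.15, my=0.0),
        2: dict(s=0.15, my=0.15),
        3: dict(s=0.15, my=0.3),
        4: dict(s=0.15, my=0.6),
        5: dict(s=0.6, my=0.0),
        6: dict(s=0.6, my=0.15),
        7: dict(s=0.6, my=0.3),
        8: dict(s=0.6, my=0.6),
    }
    row = structures[(row - 1) % 8 + 1]
    return CorrelationCondition.from_correlations(
        rho_xc=row["s"], rho_xy=row["s"], rho_cy=row["s"], rho_my=row["my"],
        scenario="b",
        strength="weak" if row["s"] == 0.15 else "strong",
        hypothesis="null1" if row["my"] == 0 else "null2",
    )


def chain_condition(strength: str) -> CorrelationCondition:
    """Scenario-b alternative with rho_XM = rho_MY = 0.6 (the power chain)."""
    s = {"weak": 0.15, "strong": 0.6}[strength]
    return CorrelationCondition.from_correlations(
        rho_xc=s, rho_xy=s, rho_cy=s, rho_xm=0.6, rho_my=0.6,
        scenario="b", strength=strength, hypothesis="alternative",
    )
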