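import numpy as np
import pytest

import treeholes as th


@pytest.fixture(scope="session")
def taxa():
    return th.default_taxa()


@pytest.fixture()
def rotifer_spec():
    return th.TaxonSpec(
        "Rotifer", "meiofauna", "box_volume",
        {"dry_wet_ratio": 0.25, "width_ratio": 0.33, "height_ratio": 0.33},
        [0.0, 0.125, 0.25, 0.5], length_unit_for_formula="um",
    )


@pytest.fixture()
def two_cup_tables(tmp_path, rotifer_spec):
    """Two-cup fixture: rotifer counts (5, 0), complete environment rows."""
    counts = tmp_path / "counts.csv"
    env = tmp_path / "env.csv"
    counts.write_text(
        "site,tree_id,date,taxon,size_class,count\n"
        "K-O,T01,2012-05,Rotifer,0,5\n"
        "K-O,T02,2012-05,Rotifer,0,0\n"
    )
    env.write_text(
        "site,tree_id,date,chl_a,afdm,o2,ph,conductivity,water_volume,"
        "last_rain,avg_daily_rain,last_frost,avg_daily_temperature\n"
        "K-O,T01,2012-05,0.5,1.2,8.1,6.4,150,300,3,1.5,40,14\n"
        "K-O,T02,2012-05,0.7,0.9,7.5,6.6,170,250,3,1.5,40,14\n"
    )
    return counts, env, {"Rotifer": rotifer_spec}


def tiny_design(n_cups: int = 40) -> th.SurveyDesign:
    """A reduced two-date design used in calibration simulations."""
    assert n_cups % 4 == 0
    return th.SurveyDesign(
        sites=("A", "B"),
        trees_per_site=n_cups // 4,
        cups_per_tree=2,
        dates=("2012-05", "2012-08"),
    )


def injected_driver_config(seed: int, effect: float | None = None,
                           taxon: str = "Bdelloidea",
                           variable: str = "chl_a") -> th.SimulationConfig:
    """Null config with a single known driver injected on one taxon."""
    if effect is None:
        effect = th.DEFAULT_INJECTED_EFFECT
    cfg = th.null_config(th.default_config(seed=seed))
    return th.inject_effect(cfg, taxon, variable, effect)


#: Eight candidate predictors: the injected driver plus seven noise variables.
CANDIDATE_VARIABLES = (
    "chl_a", "afdm", "o2", "water_volume", "last_rain",
    "avg_daily_rain", "last_frost", "avg_daily_temperature",
)
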