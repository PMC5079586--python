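"""Packaged reference data: the bacalao life history, the historical-
photograph length table, and the published per-year indicator summary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .config import life_history_from_config, load_config
from .core_data import LengthDataset, LifeHistory


def _data_path(name: str):
    return resources.files("lenassess.data").joinpath(name)


def bacalao_life_history(**overrides) -> LifeHistory:
    """Life-history parameters of the Galapagos sailfin grouper.

    L∞ = 110 cm, Lm50 = 65.3 cm, M = 0.29 /yr, M/k = 2.7, AM = 6.5 yr,
    Tmax = 21 yr.  Keyword overrides replace individual fields.
    """
    cfg = load_config(_data_path("bacalao.yaml"))
    cfg.update(overrides)
    return life_history_from_config(cfg)


def bacalao_config() -> dict:
    """The full default assessment configuration as a flat dict."""
    return load_config(_data_path("bacalao.yaml"))


def load_historical_photos() -> LengthDataset:
    """25 landed fish measured from archival photographs (1925–1938).

    Lengths were estimated photogrammetrically from eight archival images;
    only the resulting lengths ship here.  Useful as a pre-exploitation
    size reference, with the caveat that trophy-photo selection bias is
    unquantifiable.
    """
    with resources.as_file(_data_path("historical_photos.csv")) as p:
        df = pd.read_csv(p)
    return LengthDataset(df, provenance="archival photographs 1925-1938")


def load_indicator_summary() -> pd.DataFrame:
    """Published per-year indicator summary for the bacalao fishery.

    Columns: year, n (fish sampled), trips, pct_mature, pct_opt, pct_mega,
    mean_tl, sd_tl.  Percentages are printed to one decimal, so counts
    reconstructed from them are approximate.
    """
    with resources.as_file(_data_path("indicator_summary.csv")) as p:
        return pd.read_csv(p)
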