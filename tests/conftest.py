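import numpy as np
import pytest

from natmed.categorize import StrataCounts

# Published U.S. singleton-birth worked example (2016-2022): race totals and
# the two strata whose counts are printed (ELBW/EPTD and LBW/PTD).
RACE_TOTALS = {"black": (2_475_161, 21_881), "non_black": (22_973_056, 101_641)}
ELBW_EPTD = {"black": (26_163, 10_729), "non_black": (88_158, 36_779)}
LBW_PTD = {"black": (114_701, 1_614), "non_black": (647_261, 9_088)}
# controlled stratum-count posterior medians reported for those two strata
S_R_MEDIANS = {"ELBW_EPTD": {"black": 73.0, "non_black": 148.0},
               "LBW_PTD": {"black": 320.0, "non_black": 1085.0}}


@pytest.fixture(scope="session")
def published_counts() -> StrataCounts:
    """5x5 table holding the two printed strata plus explicit race totals."""
    births = np.zeros((2, 5, 5), dtype=np.int64)
    deaths = np.zeros((2, 5, 5), dtype=np.int64)
    cells = {(0, 0): ELBW_EPTD, (2, 2): LBW_PTD}
    for (i, j), d in cells.items():
        births[1, i, j], deaths[1, i, j] = d["black"]
        births[0, i, j], deaths[0, i, j] = d["non_black"]
    return StrataCounts(
        births, deaths,
        race_births=np.array([RACE_TOTALS["non_black"][0], RACE_TOTALS["black"][0]]),
        race_deaths=np.array([RACE_TOTALS["non_black"][1], RACE_TOTALS["black"][1]]),
    )
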