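"""Recognition-memory sensitivity (d-prime) under equal-variance signal detection.

d' = z(hit rate) - z(false-alarm rate), with the standard boundary
corrections so that perfect rates stay finite: a hit rate of 1 is replaced
by 1 - 1/(2 N_old) and a false-alarm rate of 0 by 1/(2 N_new).  The
symmetric cases (hit rate 0, false-alarm rate 1) receive the mirrored
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class RecognitionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_old(self) -> int:
        return self.hits + self.misses

    @property
    def n_new(self) -> int:
        return self.false_alarms + self.correct_rejections


def corrected_rates(c: RecognitionCounts) -> tuple[float, float]:
    """Hit and false-alarm rates with boundary corrections applied."""
    if c.n_old == 0 or c.n_new == 0:
        raise ValueError("need at least one OLD and one NEW trial")
    hr = c.hits / c.n_old
    far = c.false_alarms / c.n_new
    if hr == 1.0:
        hr = 1.0 - 1.0 / (2 * c.n_old)
    elif hr == 0.0:
        hr = 1.0 / (2 * c.n_old)
    if far == 0.0:
        far = 1.0 / (2 * c.n_new)
    elif far == 1.0:
        far = 1.0 - 1.0 / (2 * c.n_new)
    return hr, far


def dprime(c: RecognitionCounts) -> float:
    """Sensitivity index d' = z(HR) - z(FAR) with boundary corrections."""
    hr, far = corrected_rates(c)
    return float(norm.ppf(hr) - norm.ppf(far))


def criterion(c: RecognitionCounts) -> float:
    """Decision criterion c = -(z(HR) + z(FAR)) / 2 (reported for completeness)."""
    hr, far = corrected_rates(c)
    return float(-(norm.ppf(hr) + norm.ppf(far)) / 2.0)


def counts_from_table(table: pd.DataFrame) -> RecognitionCounts:
    """Tally hits/misses/false alarms/correct rejections from a response table.

    Expects columns ``truth`` and ``response`` with values in {"OLD", "NEW"}.
    """
    truth = table["truth"].str.upper()
    resp = table["response"].str.upper()
    bad = set(truth.unique()) | set(resp.unique()) - {"OLD", "NEW"}
    if not bad <= {"OLD", "NEW"}:
        raise ValueError(f"labels must be OLD/NEW, got {sorted(bad)}")
    return RecognitionCounts(
        hits=int(((truth == "OLD") & (resp == "OLD")).sum()),
        misses=int(((truth == "OLD") & (resp == "NEW")).sum()),
        false_alarms=int(((truth == "NEW") & (resp == "OLD")).sum()),
        correct_rejections=int(((truth == "NEW") & (resp == "NEW")).sum()),
    )


def dprime_table(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """d' per group of a long response table (e.g. by subject, session, type)."""
    rows = []
    for keys, g in table.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        c = counts_from_table(g)
        rows.append(dict(zip(by, keys)) | {
            "hits": c.hits, "false_alarms": c.false_alarms,
            "n_old": c.n_old, "n_new": c.n_new, "dprime": dprime(c),
        })
    return pd.DataFrame(rows)
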