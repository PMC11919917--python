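"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pgtdup import io as pio
from pgtdup.linkage import phase_paternal, select_informative_snps
from pgtdup.simulate import DUP_REGION


@pytest.fixture(scope="session")
def table1():
    return pio.read_table1_tsv(pio.packaged_table1_path())


@pytest.fixture(scope="session")
def dup_region():
    return DUP_REGION


@pytest.fixture(scope="session")
def phased_table1(table1, dup_region):
    informative = select_informative_snps(
        table1.calls["Male"], table1.calls["Female"], table1.calls["Proband"],
        dup_region)
    return phase_paternal(informative, table1.calls["Female"],
                          table1.calls["Proband"])


def brute_force_max_arc(values, min_bins: int = 1):
    """Exhaustive-search oracle for the maximal arc statistic.

    Loops over every arc (i, j] directly and computes the two-sample
    statistic from first principles; independent of the implementation
    it checks.
    """
    x = list(map(float, values))
    n = len(x)
    sd = float(np.std(x))
    if sd == 0 or n < 2 * min_bins:
        return 0.0, 0, n
    best = (0.0, 0, n)
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_bins or n - k < min_bins:
                continue
            arc = x[i:j]
            comp = x[:i] + x[j:]
            stat = abs(sum(arc) / k - sum(comp) / (n - k)) / (
                sd * math.sqrt(1 / k + 1 / (n - k)))
            if stat > best[0]:
                best = (stat, i, j)
    return best
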