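import numpy as np
import pandas as pd
import pytest

from immunoscape import MARKERS
from immunoscape import synthgen as sg
from immunoscape.phenotyping import assign_phenotypes, call_positivity


def make_cells(rows):
    """Minimal cell table from dicts of marker intensities.

    Unlisted markers default to the negative mean (1.0).
    """
    recs = []
    for i, r in enumerate(rows):
        rec = {"cell_id": i, "x_um": r.get("x", 0.0), "y_um": r.get("y", 0.0)}
        for m in MARKERS:
            rec[f"{m}_int"] = r.get(m, 1.0)
        recs.append(rec)
    return pd.DataFrame(recs)


def phenotyped(cells, panel=None):
    return assign_phenotypes(call_positivity(cells, panel), panel)


@pytest.fixture(scope="session")
def type1_landscape():
    cells, truth = sg.simulate_landscape(sg.single_nest_config("I", seed=11))
    return phenotyped(cells), truth


@pytest.fixture(scope="session")
def infiltrated_landscape():
    cells, truth = sg.simulate_landscape(
        sg.single_nest_config("infiltrated", seed=11))
    return phenotyped(cells), truth


@pytest.fixture(scope="session")
def random_point_cells():
    """2,000 random cells of three phenotypes for oracle-equivalence checks."""
    rng = np.random.default_rng(7)
    n = 2000
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "x_um": rng.uniform(0, 1500, n),
        "y_um": rng.uniform(0, 1500, n),
        "phenotype": rng.choice(["Tumor", "TEff", "Macrophage"], n,
                                p=[0.5, 0.3, 0.2]),
    })


def brute_force_bin_counts(cells, focal, target, edges):
    """All-pairs O(n²) oracle for distance-binned neighbor counts.

    Right-closed bins (lo, hi]; self-pairs excluded; coincident distinct
    cells fall in the first bin when it starts at 0.
    """
    edges = np.asarray(edges, float)
    xy = cells[["x_um", "y_um"]].to_numpy()
    ph = cells["phenotype"].to_numpy()
    fidx = np.flatnonzero(ph == focal)
    tidx = np.flatnonzero(ph == target)
    counts = np.zeros(len(edges) - 1)
    for i in fidx:
        for j in tidx:
            if i == j:
                continue
            d = float(np.hypot(*(xy[i] - xy[j])))
            for k in range(len(edges) - 1):
                lo, hi = edges[k], edges[k + 1]
                if (lo < d <= hi) or (d == 0.0 and k == 0 and lo == 0.0):
                    counts[k] += 1
                    break
    return counts / len(fidx)


def brute_force_neighborhood(cells, radius, phenotypes):
    """All-pairs oracle for neighborhood composition vectors."""
    xy = cells[["x_um", "y_um"]].to_numpy()
    ph = cells["phenotype"].to_numpy()
    feats = np.zeros((len(cells), len(phenotypes)), dtype=int)
    code = {p: k for k, p in enumerate(phenotypes)}
    for i in range(len(cells)):
        for j in range(len(cells)):
            if i == j:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= radius and ph[j] in code:
                feats[i, code[ph[j]]] += 1
    return feats
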