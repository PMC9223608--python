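import numpy as np
import pandas as pd
import pytest

from pdgbo import imaging as im
from pdgbo import simulate as sim

PRINTED_SERIES_M = [3e-5, 7.5e-6, 1.875e-6, 4.69e-7, 1.17e-7, 2.93e-8, 7.32e-9]


@pytest.fixture(scope="session")
def dilution_series():
    return sim.make_dilution_series(3e-5, 4.0, 7)


@pytest.fixture(scope="session")
def small_gene_sets():
    """Three 4-pathway blocks (neg/pos/mixed) of 15 genes each."""
    sets = {}
    counter = 0
    for block in ("NEG", "POS", "MIX"):
        for i in range(4):
            sets[f"{block}_{i + 1}"] = [f"G{counter + j:04d}" for j in range(15)]
            counter += 15
    return sets


def phantom_analysis(seed: int, n_cells: int = 10):
    """One rendered organoid phantom plus its full quantification."""
    truth = sim.make_image_truth(n_cells=n_cells, seed=seed)
    imgs = sim.render_organoid_images(truth, seed=seed + 100)
    result = im.analyze_image_set(imgs)
    return truth, imgs, result


@pytest.fixture(scope="session")
def phantom_panel():
    """Twenty seeded phantoms with quantification, shared across tests."""
    return [phantom_analysis(seed) for seed in range(20)]


def planted_trace_set(seed: int, n_events: int = 5, amplitude: float = 0.5,
                      noise_sd: float = 0.1):
    """One-cell trace with well-separated planted transients at a given SNR."""
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(20.0, 580.0, n_events))
    while n_events > 1 and np.diff(times).min() < 20.0:
        times = np.sort(rng.uniform(20.0, 580.0, n_events))
    truth = sim.CalciumTruth(
        event_times=[times],
        participating=np.array([True]),
        amplitude=amplitude,
        noise_sd=noise_sd,
    )
    traces = sim.simulate_calcium_traces(truth, seed=seed + 1)
    return times, traces


def simple_layout_readouts(values: dict[str, list[float]], vehicle: list[float],
                           concs: list[float] | None = None):
    """Tiny single-plate layout + readout pair for hand-checked scoring tests."""
    concs = concs or [1e-6, 4e-6]
    rows, reads = [], []
    names = iter(sim._well_names())
    for i, v in enumerate(vehicle):
        w = next(names)
        rows.append(("P1", w, "vehicle", "DMSO", np.nan, i + 1))
        reads.append(("P1", w, v))
    for drug, vals in values.items():
        for rep, per_conc in enumerate(vals, start=1):
            for c, val in zip(concs, per_conc):
                w = next(names)
                rows.append(("P1", w, "drug", drug, c, rep))
                reads.append(("P1", w, val))
    layout = pd.DataFrame(
        rows,
        columns=["plate_id", "well", "role", "drug_id", "concentration_M", "replicate"],
    )
    readouts = pd.DataFrame(reads, columns=["plate_id", "well", "readout"])
    return layout, readouts
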