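"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (ground truth, config): the same seed
and configuration reproduce the same data, and the ground truth is always
returned alongside the draw so downstream checks never need external
values.  Noise is multiplicative log-normal with unit mean (fluorescence
populations are approximately log-normal and are summarized by geometric
mean), with an optional per-replicate "day effect" multiplier emulating
measurements pooled across days.

Generated objects: Hill-shaped dose-response tables, cytometry event
clouds (a tight log-normal cell cluster plus diffuse debris, FL1 reporter
and FL3 constitutive channels, bead peaks exactly on a known calibration
line), inducer->SK-expression curves for the iso-SK design, soil
experiments mapping true nitrate spikes through a standard curve, and
protein sets with embedded GXGXG motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytometry import BeadStandard
from .hill_inference import DoseResponse, HillFit, hill_eval
from .motif_scan import ProteinRecord

__all__ = [
    "SyntheticConfig",
    "DEFAULT_DOSE_TRUTH",
    "DEFAULT_INDUCER_TRUTHS",
    "DEFAULT_SOIL_TRUTH",
    "responsive_window",
    "gen_dose_response",
    "gen_cytometry_sample",
    "gen_inducer_curves",
    "gen_soil_experiment",
    "gen_protein_set",
]

#: dose-response ground truth (low, high, K_1/2 uM, n)
DEFAULT_DOSE_TRUTH = (100.0, 10000.0, 50.0, 1.5)

#: inducer->SK-expression truths for the two iso-SK induction systems;
#: zero basal so fractional splits of a total target sum exactly
DEFAULT_INDUCER_TRUTHS = ((0.0, 1500.0, 30.0, 1.5), (0.0, 1200.0, 50.0, 1.2))

#: soil nitrate standard-curve truth (MEFL vs uM nitrate)
DEFAULT_SOIL_TRUTH = (50.0, 40000.0, 100.0, 1.5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Shared knobs for all generators.

    ``noise_cv`` is the per-measurement coefficient of variation of the
    multiplicative log-normal noise; ``day_effect_sd`` (default half the
    noise CV, hence exactly zero for noiseless configs) is the log-normal
    sd of the shared per-replicate multiplier; ``dose_span`` defaults to
    two decades either side of the truth's K_1/2; ``population_sizes`` is
    the total cytometry event count (sized so that trimming 350 events
    and gating to 10% leaves ~2000 cells, the instrument-realistic yield).
    """

    seed: int = 0
    noise_cv: float = 0.1
    n_replicates: int = 3
    n_doses: int = 12
    dose_span: tuple[float, float] | None = None
    population_sizes: int = 20350
    day_effect_sd: float | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def resolved_day_sd(self) -> float:
        return 0.5 * self.noise_cv if self.day_effect_sd is None else self.day_effect_sd


def _as_truth(truth) -> tuple[float, float, float, float]:
    if isinstance(truth, HillFit):
        return truth.low, truth.high, truth.k_half, truth.n
    low, high, k_half, n = truth
    return float(low), float(high), float(k_half), float(n)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative log-normal noise with sd/mean = cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def gen_dose_response(truth=DEFAULT_DOSE_TRUTH,
                      config: SyntheticConfig = SyntheticConfig()) -> DoseResponse:
    """Hill-shaped dose response: log-spaced doses plus a zero dose,
    ``n_replicates`` day-labelled replicates, multiplicative noise."""
    low, high, k_half, n = _as_truth(truth)
    if config.n_doses < 4:
        raise ValueError("n_doses must be >= 4")
    rng = np.random.default_rng(config.seed)
    span = config.dose_span or (k_half / 100.0, k_half * 100.0)
    doses = np.concatenate(
        [[0.0], np.logspace(np.log10(span[0]), np.log10(span[1]), config.n_doses)]
    )
    clean = hill_eval(doses, low, high, k_half, n)
    all_doses, all_resp, all_rep = [], [], []
    for rep in range(config.n_replicates):
        day = _lognormal_factor(rng, config.resolved_day_sd)
        noise = _lognormal_factor(rng, config.noise_cv, size=len(doses))
        all_doses.append(doses)
        all_resp.append(clean * day * noise)
        all_rep.append(np.full(len(doses), f"day{rep + 1}"))
    return DoseResponse(
        np.concatenate(all_doses), np.concatenate(all_resp),
        np.concatenate(all_rep),
        metadata={"truth": {"low": low, "high": high, "k_half": k_half, "n": n},
                  "config": config},
    )


# ---------------------------------------------------------------------------
# cytometry
# ---------------------------------------------------------------------------

#: default bead FL1 peak positions (detector units)
_BEAD_PEAKS = np.array([25.0, 75.0, 220.0, 650.0, 2000.0, 6000.0, 18000.0])


def gen_cytometry_sample(
    cells: tuple[float, float] = (500.0, 0.4),
    debris_fraction: float = 0.1,
    beads_line: tuple[float, float] = (1.0, 1.0),
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[pd.DataFrame, BeadStandard, np.ndarray]:
    """Synthetic event table + bead standard + per-event truth labels.

    ``cells = (median MEFL, natural-log sd)`` of the cell FL1 population;
    cell FSC/SSC are tight log-normal clusters, debris diffuse and dimmer
    in all channels.  Bead peaks lie exactly on the stated log10-log10
    line ``(slope, intercept)``; cell FL1 detector values are the MEFL
    draw pushed back through that line.  Returns (events, beads, is_cell).
    """
    median_mefl, log_sd = cells
    if not 0.0 <= debris_fraction < 1.0:
        raise ValueError("debris_fraction must be in [0, 1)")
    slope, intercept = beads_line
    n_total = int(config.population_sizes)
    n_debris = int(round(debris_fraction * n_total))
    n_cells = n_total - n_debris
    if n_cells < 1:
        raise ValueError("empty cell population")
    rng = np.random.default_rng(config.seed)

    fsc = np.concatenate([
        10 ** rng.normal(2.6, 0.04, n_cells),
        10 ** rng.normal(1.6, 0.45, n_debris),
    ])
    ssc = np.concatenate([
        10 ** rng.normal(2.4, 0.04, n_cells),
        10 ** rng.normal(1.4, 0.45, n_debris),
    ])
    cell_mefl = median_mefl * np.exp(rng.normal(0.0, log_sd, n_cells)) \
        if log_sd > 0 else np.full(n_cells, median_mefl)
    cell_fl1 = 10 ** ((np.log10(cell_mefl) - intercept) / slope)
    debris_fl1 = 10 ** rng.normal(0.4, 0.3, n_debris)
    fl1 = np.concatenate([cell_fl1, debris_fl1])
    fl3 = np.concatenate([
        10 ** rng.normal(3.0, 0.15, n_cells),
        10 ** rng.normal(0.7, 0.4, n_debris),
    ])
    is_cell = np.concatenate([np.ones(n_cells, bool), np.zeros(n_debris, bool)])

    perm = rng.permutation(n_total)
    events = pd.DataFrame({
        "order_index": np.arange(n_total),
        "fsc": fsc[perm], "ssc": ssc[perm],
        "fl1": fl1[perm], "fl3": fl3[perm],
    })
    beads = BeadStandard(_BEAD_PEAKS.copy(),
                         10 ** (intercept + slope * np.log10(_BEAD_PEAKS)))
    return events, beads, is_cell[perm]


# ---------------------------------------------------------------------------
# iso-SK inducer curves, soil, proteins
# ---------------------------------------------------------------------------


def gen_inducer_curves(
    truth1=DEFAULT_INDUCER_TRUTHS[0],
    truth2=DEFAULT_INDUCER_TRUTHS[1],
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[DoseResponse, DoseResponse]:
    """Two inducer -> SK-expression (MEFL) dose responses for the iso-SK design."""
    t1, t2 = _as_truth(truth1), _as_truth(truth2)
    cfg1 = config
    # decorrelate the two curves while keeping determinism in the one seed
    cfg2 = SyntheticConfig(**{**config.__dict__, "seed": config.seed + 104729})
    d1 = gen_dose_response(t1, _with_span(cfg1, t1))
    d2 = gen_dose_response(t2, _with_span(cfg2, t2))
    return d1, d2


def _with_span(config: SyntheticConfig, truth) -> SyntheticConfig:
    if config.dose_span is not None:
        return config
    k = truth[2]
    return SyntheticConfig(**{**config.__dict__, "dose_span": (k / 100, k * 100)})


def responsive_window(truth=DEFAULT_SOIL_TRUTH, lo_frac: float = 0.1,
                      hi_frac: float = 0.7) -> tuple[float, float]:
    """Input range over which the standard is invertible in practice:
    10-70% activation by default (above ~70% the inverse Hill amplifies
    measurement noise without bound as the curve saturates)."""
    _, _, k_half, n = _as_truth(truth)
    x_lo = k_half * (lo_frac / (1 - lo_frac)) ** (1.0 / n)
    x_hi = k_half * (hi_frac / (1 - hi_frac)) ** (1.0 / n)
    return x_lo, x_hi


def gen_soil_experiment(
    standard_truth=DEFAULT_SOIL_TRUTH,
    spikes: Sequence[float] | None = None,
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[DoseResponse, pd.DataFrame]:
    """Soil nitrate experiment: calibration dose response from the standard
    truth, plus noisy sample fluorescences at known nitrate spikes.

    Default spikes: 8 log-spaced concentrations across the standard's
    responsive window.  Returns (calibration data, samples frame with
    columns true_uM, fluorescence_mefl, replicate).
    """
    truth = _as_truth(standard_truth)
    if spikes is None:
        lo, hi = responsive_window(truth)
        spikes = np.logspace(np.log10(lo), np.log10(hi), 8)
    spikes = np.asarray(spikes, dtype=float)
    if np.any(spikes <= 0):
        raise ValueError("spikes must be > 0")
    calib = gen_dose_response(truth, _with_span(config, truth))
    rng = np.random.default_rng(config.seed + 15485863)
    rows = []
    for rep in range(config.n_replicates):
        day = _lognormal_factor(rng, config.resolved_day_sd)
        noise = _lognormal_factor(rng, config.noise_cv, size=len(spikes))
        fluor = hill_eval(spikes, *truth) * day * noise
        for s, y in zip(spikes, fluor):
            rows.append({"true_uM": s, "fluorescence_mefl": y,
                         "replicate": f"day{rep + 1}"})
    return calib, pd.DataFrame(rows)


#: default hot-spot residue distribution for synthetic SK sets
DEFAULT_HOTSPOT_DISTRIBUTION = {"L": 0.5, "A": 0.3, "T": 0.2}

_BACKGROUND_AA = "ACDEFHIKLMNPQRSTVWY"  # canonical minus G


def gen_protein_set(
    n: int,
    motif_fraction: float = 1.0,
    hotspot_distribution: Mapping[str, float] = DEFAULT_HOTSPOT_DISTRIBUTION,
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[ProteinRecord], list[dict]]:
    """Random protein set with GXGXG motifs embedded at recorded positions.

    Background residues exclude glycine, so the embedded motif is the only
    G.G.G pattern in a sequence.  A ``motif_fraction`` of records carries
    exactly one motif whose hot-spot residue is drawn from
    ``hotspot_distribution``.  Returns (records, labels) where each label
    records the embedded hot spot and its 1-based position (None if absent).
    """
    if not 0.0 <= motif_fraction <= 1.0:
        raise ValueError("motif_fraction must be in [0, 1]")
    probs = np.array(list(hotspot_distribution.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("hotspot_distribution probabilities must sum to 1")
    letters = list(hotspot_distribution.keys())
    rng = np.random.default_rng(config.seed)
    bg = np.array(list(_BACKGROUND_AA))
    records, labels = [], []
    n_motif = int(round(motif_fraction * n))
    for i in range(n):
        length = int(rng.integers(120, 400))
        seq = rng.choice(bg, size=length)
        label = {"identifier": f"synthSK_{i:05d}", "hotspot": None, "position": None}
        if i < n_motif:
            hot = letters[int(rng.choice(len(letters), p=probs))]
            x4 = str(rng.choice(bg))
            pos = int(rng.integers(10, length - 10))  # 0-based insertion point
            seq[pos:pos + 5] = list(f"G{hot}G{x4}G")
            label["hotspot"] = hot
            label["position"] = pos + 2  # 1-based hot-spot coordinate
        records.append(ProteinRecord(label["identifier"], "".join(seq)))
        labels.append(label)
    return records, labels
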