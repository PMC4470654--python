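"""Desk-scale synthetic datasets with the structure the workflow assumes.

The generator emulates a two-class quantitative phosphoproteome screen:
a sites x samples matrix of log10 ratios in which a small number of planted
"informative" sites carry a fixed between-class mean shift (default 1.0 on
the log10 scale, i.e. 10-fold) on top of i.i.d. Gaussian cell noise, entries
are missing completely at random, and a STRING-like PPI graph places the
planted proteins within two high-confidence hops of the drug target.
A validation cohort is drawn from the same model with an attenuated effect,
mimicking a domain shift between training and validation tumor types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phospho_io import (
    RESISTANT,
    SENSITIVE,
    PhosphoMatrix,
    PhosphoSite,
    PPIEdgeList,
    SampleLabels,
)


@dataclass
class SyntheticConfig:
    n_sites: int = 500
    n_train_samples: int = 20
    n_validation_samples: int = 6
    n_informative: int = 3
    effect_log10: float = 1.0        # between-class mean shift, log10 scale (10-fold)
    noise_sd: float = 0.25           # per-cell Gaussian noise, log10 scale
    missing_rate: float = 0.10       # MCAR per-cell missingness
    n_proteins: int = 400
    network_edges: int = 800         # high-confidence random edges
    n_decoy_edges: int = 150         # sub-threshold edges (dropped by the 0.9 filter)
    planted_near_target: int = 3     # informative proteins forced within <=2 hops of target
    validation_attenuation: float = 0.7  # effect multiplier for the validation cohort
    target: str = "TARGET"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_sites:
            raise ValueError("n_informative cannot exceed n_sites")
        if self.planted_near_target > self.n_informative:
            raise ValueError("planted_near_target cannot exceed n_informative")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative cannot exceed n_proteins")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.effect_log10 < 0:
            raise ValueError("noise_sd and effect_log10 must be non-negative")
        if self.n_train_samples < 4 or self.n_validation_samples < 2:
            raise ValueError("need at least 4 training and 2 validation samples")


@dataclass
class SyntheticTruth:
    informative_sites: list[str]
    class_means: dict          # site_id -> (mean_sensitive, mean_resistant)
    target_hops: dict          # planted protein -> hop count to target (1 or 2)


def _sample_labels(prefix: str, n: int) -> SampleLabels:
    n_sens = n // 2 + n % 2
    samples = [f"{prefix}{i + 1:02d}" for i in range(n)]
    y = np.array([SENSITIVE] * n_sens + [RESISTANT] * (n - n_sens))
    return SampleLabels(samples=samples, y=y)


def _sample_matrix(sites, labels, mu_sens, mu_res, noise_sd, missing_rate, rng):
    y = labels.y
    mu = np.where(y[None, :] == SENSITIVE, mu_sens[:, None], mu_res[:, None])
    values = mu + rng.normal(0.0, noise_sd, size=mu.shape)
    if missing_rate > 0:
        values = np.where(rng.random(mu.shape) < missing_rate, np.nan, values)
    return PhosphoMatrix(sites=list(sites), samples=list(labels.samples), values=values)


def generate_dataset(config: SyntheticConfig):
    """Generate (train, train_labels, validation, validation_labels, ppi, truth).

    Deterministic for a given config (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    proteins = [f"PR{i:04d}" for i in range(config.n_proteins)]

    # informative sites sit on distinct proteins 0..n_informative-1;
    # background sites are spread over the whole protein set
    site_proteins = list(proteins[: config.n_informative])
    site_proteins += [proteins[i] for i in
                      rng.integers(config.n_proteins,
                                   size=config.n_sites - config.n_informative)]
    sites = [
        PhosphoSite(site_id=f"{p}_S{100 + i}", protein_id=p, residue=f"S{100 + i}")
        for i, p in enumerate(site_proteins)
    ]

    baseline = rng.normal(0.0, 0.4, size=config.n_sites)
    effect = np.zeros(config.n_sites)
    signs = rng.choice([-1.0, 1.0], size=config.n_informative)
    effect[: config.n_informative] = signs * config.effect_log10
    mu_sens = baseline + effect / 2.0
    mu_res = baseline - effect / 2.0

    train_labels = _sample_labels("T", config.n_train_samples)
    train = _sample_matrix(sites, train_labels, mu_sens, mu_res,
                           config.noise_sd, config.missing_rate, rng)

    att = config.validation_attenuation
    val_labels = _sample_labels("V", config.n_validation_samples)
    validation = _sample_matrix(sites, val_labels,
                                baseline + att * effect / 2.0,
                                baseline - att * effect / 2.0,
                                config.noise_sd, config.missing_rate, rng)

    # --- network -----------------------------------------------------------
    best: dict[tuple[str, str], float] = {}

    def add_edge(a, b, conf):
        if a == b:
            return
        key = (a, b) if a <= b else (b, a)
        best[key] = max(best.get(key, 0.0), conf)

    target_hops: dict[str, int] = {}
    for j in range(config.planted_near_target):
        prot = proteins[j]
        if j % 2 == 0:
            add_edge(prot, config.target, 0.99)
            target_hops[prot] = 1
        else:
            hub = f"HUB{j:02d}"
            add_edge(prot, hub, 0.95)
            add_edge(hub, config.target, 0.95)
            target_hops[prot] = 2

    n_high = config.network_edges
    pairs = rng.integers(config.n_proteins, size=(n_high, 2))
    confs = rng.uniform(0.901, 0.999, size=n_high)
    for (i, j), c in zip(pairs, confs):
        add_edge(proteins[i], proteins[j], float(c))
    pairs = rng.integers(config.n_proteins, size=(config.n_decoy_edges, 2))
    confs = rng.uniform(0.5, 0.9, size=config.n_decoy_edges)
    for (i, j), c in zip(pairs, confs):
        add_edge(proteins[i], proteins[j], float(c))

    ppi = PPIEdgeList(edges=[(a, b, best[(a, b)]) for a, b in sorted(best)])

    truth = SyntheticTruth(
        informative_sites=[s.site_id for s in sites[: config.n_informative]],
        class_means={s.site_id: (float(mu_sens[i]), float(mu_res[i]))
                     for i, s in enumerate(sites[: config.n_informative])},
        target_hops=target_hops,
    )
    return train, train_labels, validation, val_labels, ppi, truth


# ---------------------------------------------------------------------------
# hand-coded toy fixture
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    matrix: PhosphoMatrix
    labels: SampleLabels
    ppi: PPIEdgeList
    target: str
    expected_distances: dict     # protein -> penalty-weighted distance to target
    missing_cells: list          # (site_id, sample_id) of the NaN entries


def make_toy_fixture() -> ToyFixture:
    """Tiny deterministic dataset for unit tests; everything checkable by hand.

    Network (confidences):  P1-T 0.999, P2-T 0.99, P3-P2 0.99, P1-P3 0.95,
    P5-P6 0.95, P4-P6 0.92. The component {P4, P5, P6} has no path to the
    target T, and protein P7 (which carries a matrix site) appears in no edge
    at all, exercising the fallback distance. Penalties: rho(0.999) = 1/3,
    rho(0.99) = 1/2, so d(P1) = 1/3, d(P2) = 1/2, d(P3) = 1 (via P2).
    Fallback = max finite distance + 1 = 2.

    The matrix has 8 sites and 6+6 samples. Sites s1 (P1) and s2 (P2) carry a
    strong class difference (~1.0 on the log10 scale); the rest are noise.
    Exactly three cells are missing: (s3, A2), (s5, B4), (s8, A6).
    """
    target = "T"
    ppi = PPIEdgeList(edges=[
        ("P1", "T", 0.999),
        ("P2", "T", 0.99),
        ("P3", "P2", 0.99),
        ("P1", "P3", 0.95),
        ("P5", "P6", 0.95),
        ("P4", "P6", 0.92),
    ])
    fallback = 2.0
    expected = {
        "T": 0.0,
        "P1": 1.0 / 3.0,
        "P2": 0.5,
        "P3": 1.0,
        "P4": fallback,
        "P5": fallback,
        "P6": fallback,
        "P7": fallback,
    }

    samples = [f"A{i}" for i in range(1, 7)] + [f"B{i}" for i in range(1, 7)]
    labels = SampleLabels(samples=samples, y=np.array([SENSITIVE] * 6 + [RESISTANT] * 6))

    sites = [
        PhosphoSite("s1", "P1", "S10"),
        PhosphoSite("s2", "P2", "S20"),
        PhosphoSite("s3", "P3", "S30"),
        PhosphoSite("s4", "P4", "S40"),
        PhosphoSite("s5", "P5", "S50"),
        PhosphoSite("s6", "P6", "S60"),
        PhosphoSite("s7", "P7", "S70"),
        PhosphoSite("s8", "P1", "S80"),
    ]
    nan = np.nan
    values = np.array([
        #  A1     A2     A3     A4     A5     A6     B1     B2     B3     B4     B5     B6
        [ 0.95,  1.10,  1.02,  0.88,  1.05,  0.99, -0.02,  0.08, -0.10,  0.05, -0.06,  0.03],  # s1 strong
        [ 0.52,  0.61,  0.48,  0.57,  0.44,  0.55, -0.49, -0.55, -0.42, -0.60, -0.51, -0.46],  # s2 strong
        [ 0.10,   nan,  0.05, -0.08,  0.12,  0.02,  0.07, -0.04,  0.09,  0.01, -0.11,  0.06],  # s3 noise
        [-0.20, -0.15, -0.25, -0.18, -0.22, -0.16, -0.21, -0.19, -0.17, -0.24, -0.14, -0.23],  # s4 flat
        [ 0.30,  0.28,  0.35,  0.31,  0.27,  0.33,  0.29,  0.32,  0.26,   nan,  0.34,  0.30],  # s5 flat
        [ 0.02, -0.05,  0.04,  0.01, -0.03,  0.00,  0.05, -0.02,  0.03, -0.04,  0.02, -0.01],  # s6 noise
        [ 0.60,  0.55,  0.65,  0.58,  0.62,  0.57,  0.61,  0.59,  0.56,  0.63,  0.54,  0.64],  # s7 flat
        [ 0.15,  0.20,  0.10,  0.18,  0.12,   nan,  0.14,  0.17,  0.11,  0.19,  0.13,  0.16],  # s8 noise
    ])
    matrix = PhosphoMatrix(sites=sites, samples=samples, values=values)
    return ToyFixture(
        matrix=matrix,
        labels=labels,
        ppi=ppi,
        target=target,
        expected_distances=expected,
        missing_cells=[("s3", "A2"), ("s5", "B4"), ("s8", "A6")],
    )
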