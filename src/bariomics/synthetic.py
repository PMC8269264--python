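"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be verified by parameter/structure recovery:

* heavy-tailed abundances — taxon intercepts are normal on the log10 scale,
  hence log-normal relative abundances after closure;
* group structure — obese samples shift a designated taxon subset;
* latent subject factors — a sparse loading matrix links per-subject
  factors to the microbiome, and the post-surgery BMI change is a linear
  function of two of those factors plus noise (signal-to-noise ratio 2 by
  default), mirroring a situation where only two projection axes carry
  outcome information;
* linear dynamics — per-subject log-abundance trajectories follow
  ``x_{t+1} = x_t + B x_t + drift + ε`` with a known sparse stable
  interaction matrix ``B`` and monotone drift injected into designated
  phyla (an increasing proteobacteria-like set, a decreasing
  firmicutes-like set);
* attrition — each post-enrollment time point is sampled with the
  probability observed in the study (66/58/23/22/9 samples over 66
  subjects).

All randomness flows from ``CohortSpec.seed``.  ``simulate_delta_pairs``
exposes the linear dynamics directly (without compositional closure), which
makes network inference an exact inverse of the generator in the noiseless
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DeltaPair
from .tables import FeatureTable, validate_metadata

#: Default per-time-point sampling probabilities (observed attrition).
DEFAULT_SCHEDULE = {"A": 1.0, "B": 0.88, "C": 0.35, "D": 0.33, "E": 0.14}

#: Mean BMI change (kg/m²) at each follow-up horizon; negative = loss.
DEFAULT_MEAN_DELTA = {"6m": -10.5, "12m": -13.0, "18m": -15.5}

_PHYLA = (
    ("Firmicutes", ("Clostridia", "Bacilli")),
    ("Bacteroidetes", ("Bacteroidia",)),
    ("Proteobacteria", ("Gammaproteobacteria", "Betaproteobacteria")),
    ("Fusobacteria", ("Fusobacteriia",)),
    ("Actinobacteria", ("Actinobacteria",)),
)


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults encode the emulated study: 83 lean controls sampled once, 66
    obese subjects sampled at up to five time points with attrition,
    enrollment BMI 43.3 ± 6.8 for the obese and uniform 19–25 for the lean,
    five latent factors of decreasing scale, and an outcome loading only on
    factors 1 and 5.
    """

    n_lean: int = 83
    n_obese: int = 66
    timepoint_schedule: dict = field(default_factory=lambda: dict(DEFAULT_SCHEDULE))
    followup_prob: float = 1.0
    n_taxa: int = 70
    n_latent_factors: int = 5
    factor_loading_sparsity: float = 0.15
    factor_block_sizes: tuple | None = (14, 8, 6, 4, 12)
    factor_scales: tuple = (0.82, 0.108, 0.089, 0.075, 0.333)
    group_effect_size: float = 0.5
    n_group_taxa: int = 18
    outcome_weights: tuple = (3.5, 0.0, 0.0, 0.0, 3.5)
    outcome_snr: float = 2.0
    mean_outcome_delta: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_DELTA))
    intercept_sd: float = 0.8
    noise_sd: float = 0.045
    interaction_matrix: np.ndarray | None = None
    interaction_density: float = 0.03
    interaction_strength: float = 0.15
    self_decay: float = 0.3
    dynamics_noise_sd: float = 0.0075
    trend_magnitude: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.factor_scales) != self.n_latent_factors:
            raise ValueError("factor_scales length must equal n_latent_factors")
        if len(self.outcome_weights) != self.n_latent_factors:
            raise ValueError("outcome_weights length must equal n_latent_factors")
        for code, p in self.timepoint_schedule.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sampling probability for {code} outside [0,1]")

    @property
    def outcome_noise_sd(self) -> float:
        """Noise SD implied by the signal variance and the target SNR."""
        signal_var = float(np.sum(np.square(self.outcome_weights)))
        return float(np.sqrt(signal_var / self.outcome_snr))


def random_interaction_matrix(n_taxa: int, density: float = 0.03,
                              strength: float = 0.15, self_decay: float = 0.3,
                              seed: int = 0, max_attempts: int = 100) -> np.ndarray:
    """Sparse signed interaction matrix with a stable update ``I + B``.

    Diagonal entries are ``-self_decay`` (every taxon damps itself);
    off-diagonal entries are ±``strength`` with probability ``density``.
    Draws are rejection-sampled until the spectral radius of ``I + B``
    stays at or below 1 (deterministic given the seed); an error after
    ``max_attempts`` draws signals parameters that are simply too strong.
    """
    rng = np.random.default_rng(seed)
    last_error = None
    for _ in range(max_attempts):
        B = np.zeros((n_taxa, n_taxa))
        mask = rng.random((n_taxa, n_taxa)) < density
        np.fill_diagonal(mask, False)
        signs = rng.choice([-1.0, 1.0], size=(n_taxa, n_taxa))
        B[mask] = (signs * strength)[mask]
        np.fill_diagonal(B, -self_decay)
        try:
            check_stability(B)
            return B
        except ValueError as exc:
            last_error = exc
    raise ValueError(
        f"no stable draw in {max_attempts} attempts "
        f"(density={density}, strength={strength}): {last_error}")


def check_stability(B: np.ndarray) -> None:
    """Reject matrices whose update ``I + B`` amplifies perturbations.

    The boundary case (radius exactly 1, e.g. ``B = 0``: a random walk) is
    allowed — short trajectories stay bounded and the no-interaction null
    is a legitimate simulation condition.
    """
    radius = float(np.max(np.abs(np.linalg.eigvals(np.eye(len(B)) + B))))
    if radius > 1.0 + 1e-9:
        raise ValueError(f"unstable interaction matrix: spectral radius {radius:.3f} > 1")


def _taxonomy(n_taxa: int) -> tuple[list[str], dict[str, str], dict[str, str]]:
    """Feature ids, lineages, and feature→phylum map for synthetic taxa."""
    feature_ids, lineages, phylum_of = [], {}, {}
    for i in range(n_taxa):
        phylum, classes = _PHYLA[i % len(_PHYLA)]
        cls = classes[(i // len(_PHYLA)) % len(classes)]
        fid = f"F{i:03d}"
        lineage = (f"k__Bacteria; p__{phylum}; c__{cls}; o__Order{i % 7}; "
                   f"f__Family{i % 13:02d}; g__Genus{i:03d}")
        feature_ids.append(fid)
        lineages[fid] = lineage
        phylum_of[fid] = phylum
    return feature_ids, lineages, phylum_of


def generate_cohort(spec: CohortSpec | None = None
                    ) -> tuple[FeatureTable, pd.DataFrame, dict]:
    """Simulate a longitudinal cohort; returns (raw table, metadata, truth).

    The ground-truth record carries the subject factors, factor loadings,
    interaction matrix, group-affected taxa, trend-injected taxa and
    outcome weights, for use by recovery tests.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n_taxa, k = spec.n_taxa, spec.n_latent_factors
    feature_ids, lineages, phylum_of = _taxonomy(n_taxa)

    B = spec.interaction_matrix
    if B is None:
        B = random_interaction_matrix(
            n_taxa, spec.interaction_density, spec.interaction_strength,
            spec.self_decay, seed=int(rng.integers(2**31)))
    else:
        B = np.asarray(B, dtype=float)
        check_stability(B)

    # sparse factor loadings: disjoint taxon blocks, one per factor, so the
    # factor directions are orthogonal and identifiable by the decomposition;
    # block sizes decrease across factors, which separates the factor
    # eigenvalues (eigenvalue ~ block size x per-taxon variance share) and
    # keeps the fitted components from rotating within degenerate subspaces
    loadings = np.zeros((n_taxa, k))
    if spec.factor_block_sizes is not None and len(spec.factor_block_sizes) == k \
            and sum(spec.factor_block_sizes) <= n_taxa:
        sizes = list(spec.factor_block_sizes)
    else:
        base = max(2, min(int(round(spec.factor_loading_sparsity * n_taxa)),
                          n_taxa // k))
        if k > 1:
            sizes = [max(2, int(round(base * (1.5 - j / (k - 1)))))
                     for j in range(k)]
        else:
            sizes = [base]
    # draw intercepts first: factor blocks avoid the most abundant taxa, so
    # the per-sample closure total (dominated by those taxa) stays
    # uncorrelated with the latent factors
    intercepts = rng.normal(-1.0, spec.intercept_sd, size=n_taxa)
    n_dominant = min(6, max(0, n_taxa - sum(sizes)))
    eligible = np.argsort(intercepts)[:n_taxa - n_dominant]
    permuted = rng.permutation(eligible)
    offset = 0
    for j in range(k):
        idx = permuted[offset:offset + sizes[j]]
        offset += sizes[j]
        col = np.zeros(n_taxa)
        # equal-magnitude signed entries spread the factor evenly over its
        # block; signs are balanced greedily against taxon abundance so the
        # factor leaves the per-sample total (the closure denominator)
        # untouched to first order and stays decoupled from the size axis
        weights = np.power(10.0, intercepts[idx])
        order = np.argsort(-weights)
        signs = np.zeros(len(idx))
        running = 0.0
        for pos in order:
            signs[pos] = -1.0 if running > 0 else 1.0
            running += signs[pos] * weights[pos]
        col[idx] = signs
        loadings[:, j] = spec.factor_scales[j] * col / np.linalg.norm(col)

    # the lean/obese shift lives on taxa outside the factor blocks and away
    # from the dominant taxa, so group structure, latent factors and the
    # per-sample closure total occupy different axes
    taken = set(permuted[:offset].tolist())
    dominant = set(np.argsort(intercepts)[n_taxa - n_dominant:].tolist())
    unloaded = np.array([i for i in range(n_taxa)
                         if i not in taken and i not in dominant])
    if len(unloaded) >= spec.n_group_taxa:
        group_taxa = rng.choice(unloaded, size=spec.n_group_taxa, replace=False)
    else:
        group_taxa = rng.choice(n_taxa, size=min(spec.n_group_taxa, n_taxa),
                                replace=False)

    # monotone drift injected by phylum, emulating post-surgery trends
    drift = np.zeros(n_taxa)
    up = [i for i, f in enumerate(feature_ids)
          if phylum_of[f] in ("Proteobacteria", "Fusobacteria")]
    down = [i for i, f in enumerate(feature_ids) if phylum_of[f] == "Firmicutes"]
    drift[up] = spec.trend_magnitude
    drift[down] = -spec.trend_magnitude

    subjects, factors = [], []
    rows, meta_rows = [], []

    def add_sample(sample_id, subject_id, tp, log_abund, bmi, a1c, age, gender,
                   followups):
        freq = np.power(10.0, log_abund)
        freq = freq / freq.sum()
        rows.append((sample_id, freq))
        meta_rows.append({
            "sample_id": sample_id, "subject_id": subject_id, "timepoint": tp,
            "bmi": round(float(bmi), 2),
            "a1c": round(float(a1c), 2) if a1c is not None else np.nan,
            "age": float(age), "gender": int(gender),
            "bmi_6m": followups.get("6m", np.nan),
            "bmi_12m": followups.get("12m", np.nan),
            "bmi_18m": followups.get("18m", np.nan),
        })

    # --- obese subjects: longitudinal trajectories + outcome ------------
    outcome_noise = spec.outcome_noise_sd
    w = np.asarray(spec.outcome_weights, dtype=float)
    truth_outcome = {}
    for s in range(spec.n_obese):
        subject_id = f"O{s + 1:03d}"
        f = rng.normal(size=k)
        subjects.append(subject_id)
        factors.append(f)

        base_mean = intercepts.copy()
        base_mean[group_taxa] += spec.group_effect_size
        dev = loadings @ f + rng.normal(0, spec.noise_sd, n_taxa)

        bmi_a = float(np.clip(rng.normal(43.3, 6.8), 35.5, 70.0))
        a1c_a = rng.normal(6.5, 0.4)
        age = float(np.clip(rng.normal(48, 12), 18, 70))
        gender = rng.random() < 0.71

        signal = float(w @ f)
        deltas = {h: spec.mean_outcome_delta[h] + signal + rng.normal(0, outcome_noise)
                  for h in spec.mean_outcome_delta}
        followups = {}
        for h, d in deltas.items():
            if rng.random() < spec.followup_prob:
                followups[h] = round(max(bmi_a + d, 19.0), 2)
        truth_outcome[subject_id] = deltas

        # BMI/A1C trajectory across sampled visits (descriptive only)
        visit_bmi = {"A": bmi_a, "B": bmi_a - 2.0, "C": bmi_a - 5.0,
                     "D": bmi_a - 8.5, "E": bmi_a + deltas["6m"]}
        visit_a1c = {"A": a1c_a, "B": a1c_a - 0.1, "C": a1c_a - 0.3,
                     "D": a1c_a - 0.5, "E": a1c_a - 0.7}

        # dynamics act on the deviation from the subject-invariant baseline:
        # x_{t+1} - x_t = B (x_t - base_mean) + drift + eps, so the delta
        # regression sees B exactly (the constant term folds into its intercept)
        for t, code in enumerate(("A", "B", "C", "D", "E")):
            sampled = rng.random() < spec.timepoint_schedule.get(code, 0.0)
            if sampled:
                add_sample(f"{subject_id}_{code}", subject_id, code,
                           base_mean + dev,
                           max(visit_bmi[code], 20.0), visit_a1c[code],
                           age, gender, followups)
            dev = dev + B @ dev + drift + rng.normal(
                0, spec.dynamics_noise_sd, n_taxa)

    # --- lean controls: one sample each ---------------------------------
    for s in range(spec.n_lean):
        subject_id = f"L{s + 1:03d}"
        f = rng.normal(size=k)
        subjects.append(subject_id)
        factors.append(f)
        base = intercepts + loadings @ f + rng.normal(0, spec.noise_sd, n_taxa)
        bmi = rng.uniform(19.0, 25.0)  # lean controls carry no group shift
        a1c = rng.normal(4.6, 0.25)
        age = float(np.clip(rng.normal(36, 12), 18, 70))
        gender = rng.random() < 0.5
        add_sample(f"{subject_id}_H", subject_id, "H", base, bmi, a1c,
                   age, gender, {})

    data = pd.DataFrame(
        {sid: freq for sid, freq in rows}, index=feature_ids
    ).T
    data.index.name = "sample_id"
    table = FeatureTable(data=data, taxonomy=lineages, stage="raw")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta = validate_metadata(meta)

    truth = {
        "factors": pd.DataFrame(np.array(factors), index=subjects,
                                columns=[f"factor{j + 1}" for j in range(k)]),
        "loadings": loadings,
        "interaction_matrix": B,
        "group_taxa": [feature_ids[i] for i in group_taxa],
        "trend_up_taxa": [feature_ids[i] for i in up],
        "trend_down_taxa": [feature_ids[i] for i in down],
        "outcome_weights": w,
        "outcome_noise_sd": outcome_noise,
        "outcome_deltas": truth_outcome,
        "drift": drift,
    }
    return table, meta, truth


# ---------------------------------------------------------------------------
# deterministic toy fixture
# ---------------------------------------------------------------------------

_TOY_LINEAGES = {
    "F1": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Faecalibacterium",
    "F2": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Faecalibacterium",
    "F3": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__S24-7; g__",
    "F4": "k__Bacteria; p__Actinobacteria; c__Coriobacteriia; o__Coriobacteriales; f__Coriobacteriaceae; g__Collinsella",
    "F5": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Enterobacteriales; f__Enterobacteriaceae; g__Escherichia",
    "F6": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Bacteroidaceae; g__Bacteroides",
    "F7": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Lactobacillaceae; g__Lactobacillus",
    "F8": "k__Bacteria; p__Fusobacteria; c__Fusobacteriia; o__Fusobacteriales; f__Fusobacteriaceae; g__Fusobacterium",
}

# 17 samples × 8 features; F4 is nonzero in exactly 4 samples (prevalence
# casualty at min 5), F3 is an S24-7 contaminant, F1+F2 share a genus and
# collapse to their mean, F6 is constant (zero-variance convention).
_TOY_VALUES = {
    "F1": [2, 4, 0, 2, 6, 2, 4, 2, 0, 2, 4, 6, 2, 4, 2, 0, 2],
    "F2": [4, 2, 2, 4, 2, 4, 2, 4, 2, 4, 2, 2, 4, 2, 4, 2, 4],
    "F3": [1] * 17,
    "F4": [0.9, 0, 0, 9.9, 0, 0, 0, 0, 0, 0.5, 0, 0, 0, 0, 0, 0.2, 0],
    "F5": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 0.9, 9.9, 1, 2, 3, 4, 5],
    "F6": [5] * 17,
    "F7": [0.9, 9.9, 0, 0.9, 9.9, 0, 0.9, 9.9, 0, 0.9, 9.9, 0, 0.9, 9.9, 0, 0.9, 9.9],
    "F8": [1, 0, 3, 0, 5, 0, 7, 0, 9, 0, 2, 0, 4, 0, 6, 0, 8],
}

_TOY_SAMPLES = [
    # (sample_id, subject_id, timepoint, bmi, a1c, age, gender, bmi_6m)
    ("S01_A", "S01", "A", 43.3, 6.5, 52, 1, 33.0),
    ("S01_B", "S01", "B", 41.1, 6.4, 52, 1, 33.0),
    ("S02_A", "S02", "A", 39.8, 6.9, 45, 0, 30.5),
    ("S02_B", "S02", "B", 38.0, 6.7, 45, 0, 30.5),
    ("S03_A", "S03", "A", 47.2, None, 61, 1, 35.1),
    ("S03_C", "S03", "C", 44.0, None, 61, 1, 35.1),
    ("S04_A", "S04", "A", 36.4, 5.9, 33, 1, 28.0),
    ("S04_D", "S04", "D", 30.2, 5.6, 33, 1, 28.0),
    ("S05_A", "S05", "A", 51.0, 7.2, 58, 0, 38.9),
    ("S05_E", "S05", "E", 38.9, 6.1, 58, 0, 38.9),
    ("S06_A", "S06", "A", 42.5, 6.3, 49, 1, None),
    ("S07_B", "S07", "B", 40.7, 6.6, 38, 0, None),
    ("S08_A", "S08", "A", 44.9, 6.8, 55, 1, None),
    ("L01_H", "L01", "H", 22.1, 4.7, 29, 0, None),
    ("L02_H", "L02", "H", 23.8, 4.5, 41, 1, None),
    ("L03_H", "L03", "H", 20.9, 4.9, 35, 1, None),
    ("L04_H", "L04", "H", 24.6, 4.4, 27, 0, None),
]


def generate_toy_fixture() -> tuple[FeatureTable, pd.DataFrame]:
    """Deterministic 12-subject, 8-taxon fixture with hand-checkable arithmetic.

    Built from literal values (no RNG): eight obese subjects across time
    points A–E plus four lean controls (H).  The normalization chain over it
    is fully hand-computable: genus collapse merges F1+F2, the contaminant
    filter removes the S24-7 feature, and the prevalence filter (min 5)
    removes F4's genus, leaving 5 surviving taxa.
    """
    data = pd.DataFrame(
        {fid: np.asarray(vals, dtype=float) for fid, vals in _TOY_VALUES.items()},
        index=[s[0] for s in _TOY_SAMPLES],
    )
    data.index.name = "sample_id"
    table = FeatureTable(data=data, taxonomy=dict(_TOY_LINEAGES), stage="raw")
    meta = pd.DataFrame(
        [{"sample_id": sid, "subject_id": sub, "timepoint": tp, "bmi": bmi,
          "a1c": np.nan if a1c is None else a1c, "age": age, "gender": gender,
          "bmi_6m": np.nan if fu is None else fu,
          "bmi_12m": np.nan, "bmi_18m": np.nan}
         for sid, sub, tp, bmi, a1c, age, gender, fu in _TOY_SAMPLES]
    ).set_index("sample_id")
    return table, validate_metadata(meta)


def write_toy_fixture(directory) -> None:
    """Write the toy fixture as the three TSVs the readers consume."""
    from pathlib import Path

    from .tables import write_feature_table, write_metadata

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, meta = generate_toy_fixture()
    write_feature_table(table, directory / "feature_table.tsv",
                        taxonomy_path=directory / "taxonomy.tsv")
    write_metadata(meta, directory / "metadata.tsv")


def load_toy_fixture() -> tuple[FeatureTable, pd.DataFrame]:
    """Load the committed copy of the toy fixture from package data."""
    from importlib import resources

    from .tables import read_feature_table, read_metadata

    root = resources.files("bariomics") / "data" / "toy"
    table = read_feature_table(str(root / "feature_table.tsv"),
                               taxonomy_path=str(root / "taxonomy.tsv"))
    meta = read_metadata(str(root / "metadata.tsv"))
    return table, meta


def simulate_delta_pairs(B: np.ndarray, n_pairs: int, noise_sd: float = 0.0,
                         seed: int = 0, n_timepoints: int = 5,
                         x0_sd: float = 1.0) -> tuple[list[DeltaPair], list[str]]:
    """Delta pairs straight from the linear dynamics, no compositional closure.

    Subjects start at ``x0 ~ N(0, x0_sd²)`` and evolve by
    ``x_{t+1} = x_t + B x_t + ε`` for ``n_timepoints`` visits, yielding
    ``n_timepoints − 1`` pairs each, until ``n_pairs`` pairs exist.  In the
    noiseless case, OLS of delta on level recovers ``B`` exactly — the
    analytic oracle for network inference.
    """
    B = np.asarray(B, dtype=float)
    n_taxa = len(B)
    check_stability(B)
    rng = np.random.default_rng(seed)
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    codes = ("A", "B", "C", "D", "E")[:n_timepoints]
    pairs: list[DeltaPair] = []
    subject = 0
    while len(pairs) < n_pairs:
        subject += 1
        x = rng.normal(0, x0_sd, n_taxa)
        for t in range(n_timepoints - 1):
            step = B @ x + rng.normal(0, noise_sd, n_taxa)
            pairs.append(DeltaPair(
                subject_id=f"S{subject:04d}", t_from=codes[t], t_to=codes[t + 1],
                x_from=x.copy(), delta=step))
            x = x + step
            if len(pairs) == n_pairs:
                break
    return pairs, taxa
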