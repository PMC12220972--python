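"""Synthetic paired scRNA/scTCR repertoire generator with known ground truth.

The generator emulates the structure of a multi-patient bladder-cancer
T cell study: per patient, clones are drawn with a geometric size law,
tumor clones seed blood cells with a phenotype-dependent sharing
probability (cytotoxic phenotypes share most), and every cell receives
marker-gene counts from a negative binomial whose mean depends on the
cell's phenotype, with an anti-PD-L1 treatment effect that raises MKI67
and lowers KLRG1 in cytotoxic clones after treatment.  Chain-level
clonotype calls are emitted separately with configurable tie and
dropout noise so the resolution stage can be tested against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

PHENOTYPES: tuple[str, ...] = (
    "Naive", "GZMB+", "Mito", "CM", "GZMK+", "CXCL13+",
    "Treg", "Prolif", "MAIT", "EA", "IFN",
)
CYTOTOXIC_PHENOTYPES = frozenset({"GZMB+", "GZMK+", "Prolif", "MAIT"})
COMPARTMENTS = ("blood", "tumor", "NAT")
LINEAGES = ("CD4", "CD8")

MARKER_GENES = (
    "GZMB", "GZMK", "MKI67", "KLRG1", "CCR7", "SELL",
    "IL7R", "FOXP3", "CXCL13", "SLC4A10", "IFIT1", "CYCS",
)
MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Phenotype frequency tables (per compartment).  Blood is dominated by
# naive/memory cells with a minority of cytotoxic CD4-like phenotypes;
# tumor is enriched for GZMK+, CXCL13+ and Tregs.
_BLOOD_FREQS = {
    "Naive": 0.30, "CM": 0.20, "GZMB+": 0.06, "GZMK+": 0.05, "Treg": 0.08,
    "CXCL13+": 0.02, "Prolif": 0.03, "MAIT": 0.04, "EA": 0.08, "IFN": 0.04,
    "Mito": 0.10,
}
_TUMOR_FREQS = {
    "Naive": 0.05, "CM": 0.10, "GZMB+": 0.08, "GZMK+": 0.15, "Treg": 0.18,
    "CXCL13+": 0.15, "Prolif": 0.08, "MAIT": 0.03, "EA": 0.08, "IFN": 0.04,
    "Mito": 0.06,
}

# Probability that a tumor clone also seeds blood cells.  Cytotoxic
# phenotypes dominate the blood-tumor shared repertoire.
_SHARE_PROB = {
    "GZMB+": 0.40, "GZMK+": 0.30, "Prolif": 0.30, "MAIT": 0.25,
    "Naive": 0.05, "CM": 0.05, "Treg": 0.05, "CXCL13+": 0.05,
    "EA": 0.05, "IFN": 0.05, "Mito": 0.05,
}

# Marker-gene mean counts: base vector plus phenotype-specific overrides.
_BASE_MARKER_MEAN = 0.3
_MARKER_OVERRIDES: dict[str, dict[str, float]] = {
    "Naive": {"CCR7": 5.0, "SELL": 5.0, "IL7R": 4.0, "MKI67": 0.1, "GZMB": 0.05, "GZMK": 0.05},
    "CM": {"CCR7": 4.0, "IL7R": 3.0, "SELL": 2.0},
    "GZMB+": {"GZMB": 8.0, "KLRG1": 4.0, "GZMK": 0.3},
    "GZMK+": {"GZMK": 8.0, "KLRG1": 3.0, "GZMB": 0.5},
    "Prolif": {"MKI67": 8.0, "GZMB": 3.0, "GZMK": 3.0, "KLRG1": 1.0},
    "MAIT": {"SLC4A10": 5.0, "GZMK": 3.0, "KLRG1": 2.0},
    "Treg": {"FOXP3": 5.0, "IL7R": 0.5},
    "CXCL13+": {"CXCL13": 6.0},
    "EA": {"CYCS": 5.0},
    "IFN": {"IFIT1": 6.0},
    "Mito": {},
}
_MITO_MEAN = 0.6
_MITO_PHENOTYPE_BOOST = 2.2  # Mito phenotype sits near the 10% QC boundary


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PostTreatmentShift:
    """Expression/phenotype shift applied to cytotoxic clones after treatment.

    mki67_multiplier / klrg1_multiplier scale the negative-binomial means
    of MKI67 and KLRG1 in post-treatment cells of cytotoxic clones;
    prolif_conversion is the probability that such a cell is relabeled
    Prolif (clonal phenotype plasticity under PD-1/PD-L1 blockade).
    """

    mki67_multiplier: float = 4.0
    klrg1_multiplier: float = 0.25
    prolif_conversion: float = 0.25


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 6
    cells_per_compartment: Mapping[str, int] = field(
        default_factory=lambda: {"blood": 2000, "tumor": 600, "NAT": 0}
    )
    timepoints: tuple[str, ...] = ("pre", "post")
    phenotype_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"blood": dict(_BLOOD_FREQS), "tumor": dict(_TUMOR_FREQS)}
    )
    lineage_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"CD4": 0.6, "CD8": 0.4}
    )
    clone_size_p: float = 0.65
    shared_blood_r: int = 3
    share_prob: Mapping[str, float] = field(default_factory=lambda: dict(_SHARE_PROB))
    post_treatment_shift: PostTreatmentShift = PostTreatmentShift()
    marker_means: Mapping[str, Mapping[str, float]] | None = None
    tie_rate: float = 0.05
    chain_dropout: float = 0.30
    minor_call_rate: float = 0.10
    high_mito_rate: float = 0.02
    mito_boost: float = 6.0
    nb_dispersion: float = 2.0
    n_filler_genes: int = 30
    filler_mean: float = 1.0
    seed: int = 0

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be > 0")
        for comp, n in self.cells_per_compartment.items():
            if comp not in COMPARTMENTS:
                raise ConfigError(f"unknown compartment {comp!r}")
            if n < 0:
                raise ConfigError(f"cells_per_compartment[{comp!r}] must be >= 0")
        if sum(self.cells_per_compartment.values()) <= 0:
            raise ConfigError("at least one compartment must have cells")
        if set(self.timepoints) - {"pre", "post", "untreated"}:
            raise ConfigError(f"invalid timepoints {self.timepoints!r}")
        for comp, freqs in self.phenotype_freqs.items():
            vec = np.array([freqs.get(p, 0.0) for p in PHENOTYPES], dtype=float)
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ConfigError(f"phenotype_freqs[{comp!r}] must sum to 1")
        lin = np.array([self.lineage_freqs.get(l, 0.0) for l in LINEAGES])
        if (lin < 0).any() or abs(lin.sum() - 1.0) > 1e-9:
            raise ConfigError("lineage_freqs must sum to 1")
        if not (0 < self.clone_size_p <= 1):
            raise ConfigError("clone_size_p must be in (0, 1]")
        if self.shared_blood_r < 1:
            raise ConfigError("shared_blood_r must be >= 1")
        for phen, p in self.share_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"share_prob[{phen!r}] must be a probability")
        for name in ("tie_rate", "chain_dropout", "minor_call_rate", "high_mito_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")


@dataclass
class GroundTruth:
    """True clonal structure of a simulated dataset.

    clones: one row per clone (index clone_id) with patient, lineage,
        phenotype of origin, both CDR3s, realized per-compartment cell
        counts, and the shared flag (>=1 blood cell AND >=1 tumor cell).
    cell_to_clone: Series mapping every simulated cell_id to its clone.
    """

    clones: pd.DataFrame
    cell_to_clone: pd.Series

    def shared_flag_of_cells(self, cell_ids: Sequence[str]) -> np.ndarray:
        clone_ids = self.cell_to_clone.loc[list(cell_ids)]
        return self.clones.loc[clone_ids, "shared"].to_numpy(dtype=bool)

    def to_json(self, path) -> None:
        payload = {
            "clones": self.clones.reset_index().to_dict(orient="list"),
            "cell_to_clone": {
                "cell_id": self.cell_to_clone.index.tolist(),
                "clone_id": self.cell_to_clone.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        clones = pd.DataFrame(payload["clones"]).set_index("clone_id")
        c2c = pd.Series(
            payload["cell_to_clone"]["clone_id"],
            index=payload["cell_to_clone"]["cell_id"],
            name="clone_id",
        )
        return cls(clones=clones, cell_to_clone=c2c)


def _patient_rng(config: SimConfig, patient_index: int, stream: int = 0) -> np.random.Generator:
    # one independent, reproducible stream per patient
    return np.random.default_rng([config.seed, patient_index, stream])


def _random_cdr3(rng: np.random.Generator, prefix: str, suffix: str) -> str:
    n = int(rng.integers(8, 21)) - len(prefix) - len(suffix)
    body = "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), size=n))
    return prefix + body + suffix


def _batch_cdr3(rng: np.random.Generator, n: int, prefix: str, suffix: str) -> list[str]:
    """Random junctions, total length 8-20 aa with fixed prefix/suffix motifs."""
    fixed = len(prefix) + len(suffix)
    body_len = rng.integers(8, 21, size=n) - fixed
    letters = rng.integers(0, len(AA_ALPHABET), size=int(body_len.sum()))
    out, pos = [], 0
    for length in body_len:
        out.append(prefix + "".join(AA_ALPHABET[i] for i in letters[pos:pos + length]) + suffix)
        pos += length
    return out


def _batch_clonotypes(rng: np.random.Generator, n: int,
                      used: set[tuple[str, str]]) -> tuple[list[str], list[str]]:
    """n unique (cdr3a, cdr3b) pairs; collisions rejected and resampled."""
    alphas = _batch_cdr3(rng, n, "CA", "F")
    betas = _batch_cdr3(rng, n, "CASS", "F")
    for i in range(n):
        pair = (alphas[i], betas[i])
        while pair in used:
            pair = (_random_cdr3(rng, "CA", "F"), _random_cdr3(rng, "CASS", "F"))
        used.add(pair)
        alphas[i], betas[i] = pair
    return alphas, betas


def _fill_sizes(rng: np.random.Generator, p: float, quota: int) -> np.ndarray:
    """Geometric clone sizes that sum exactly to ``quota`` (last truncated)."""
    if quota <= 0:
        return np.empty(0, dtype=np.int64)
    sizes = rng.geometric(p, size=quota)
    cum = np.cumsum(sizes)
    k = int(np.searchsorted(cum, quota))
    sizes = sizes[:k + 1].copy()
    sizes[-1] -= int(cum[k] - quota)
    return sizes


def _freq_vector(config: SimConfig, compartment: str) -> np.ndarray:
    table = config.phenotype_freqs.get(compartment)
    if table is None:  # NAT falls back to the tumor table
        table = config.phenotype_freqs["tumor"]
    return np.array([table.get(p, 0.0) for p in PHENOTYPES], dtype=float)


def _simulate_patient(config: SimConfig, p_idx: int, used_cdr3: set
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (clones, cells) DataFrames for one patient (vectorized)."""
    rng = _patient_rng(config, p_idx)
    patient = f"P{p_idx + 1:02d}"
    treated = set(config.timepoints) >= {"pre", "post"}
    lin_p = np.array([config.lineage_freqs.get(l, 0.0) for l in LINEAGES])
    p = config.clone_size_p
    quota_tumor = int(config.cells_per_compartment.get("tumor", 0))
    quota_blood = int(config.cells_per_compartment.get("blood", 0))
    quota_nat = int(config.cells_per_compartment.get("NAT", 0))
    share_vec = np.array([config.share_prob.get(ph, 0.0) for ph in PHENOTYPES])

    # --- tumor clones (may also seed blood) --------------------------
    t_sizes = _fill_sizes(rng, p, quota_tumor)
    nt = len(t_sizes)
    t_phen = rng.choice(len(PHENOTYPES), size=nt, p=_freq_vector(config, "tumor"))
    t_lin = rng.choice(len(LINEAGES), size=nt, p=lin_p)
    shared_intent = rng.random(nt) < share_vec[t_phen]
    # tumor-matched clones are clonally expanded in blood: r geometric draws
    shared_blood = np.where(
        shared_intent,
        rng.geometric(p, size=(nt, config.shared_blood_r)).sum(axis=1), 0
    )
    # allocate shared blood cells in clone order, capped by the blood quota
    cum = np.cumsum(shared_blood)
    t_blood = np.minimum(shared_blood, np.maximum(0, quota_blood - (cum - shared_blood)))
    used_blood = int(t_blood.sum())

    # --- blood-only clones, then NAT-only clones ---------------------
    b_sizes = _fill_sizes(rng, p, quota_blood - used_blood)
    nb = len(b_sizes)
    b_phen = rng.choice(len(PHENOTYPES), size=nb, p=_freq_vector(config, "blood"))
    b_lin = rng.choice(len(LINEAGES), size=nb, p=lin_p)
    n_sizes = _fill_sizes(rng, p, quota_nat)
    nn = len(n_sizes)
    n_phen = rng.choice(len(PHENOTYPES), size=nn, p=_freq_vector(config, "NAT"))
    n_lin = rng.choice(len(LINEAGES), size=nn, p=lin_p)

    n_clones = nt + nb + nn
    alphas, betas = _batch_clonotypes(rng, n_clones, used_cdr3)
    clone_phen = np.concatenate([t_phen, b_phen, n_phen]).astype(int)
    clone_lin = np.concatenate([t_lin, b_lin, n_lin]).astype(int)
    clones = pd.DataFrame({
        "clone_id": [f"{patient}_CL{i:05d}" for i in range(n_clones)],
        "patient_id": patient,
        "lineage": np.array(LINEAGES)[clone_lin],
        "phenotype": np.array(PHENOTYPES)[clone_phen],
        "cdr3a": alphas, "cdr3b": betas,
        "n_blood": np.concatenate([t_blood, b_sizes, np.zeros(nn, int)]),
        "n_tumor": np.concatenate([t_sizes, np.zeros(nb + nn, int)]),
        "n_nat": np.concatenate([np.zeros(nt + nb, int), n_sizes]),
    })

    # --- cells: tumor block, blood block, NAT block ------------------
    blocks = [
        ("tumor", np.repeat(np.arange(nt), t_sizes)),
        ("blood", np.repeat(np.arange(n_clones), clones["n_blood"].to_numpy())),
        ("NAT", np.repeat(np.arange(nt + nb, n_clones), n_sizes)),
    ]
    comp = np.concatenate([np.full(len(ix), name) for name, ix in blocks])
    clone_ix = np.concatenate([ix for _, ix in blocks])
    n_cells = len(clone_ix)
    if treated:
        tps = np.where(comp == "blood",
                       np.where(rng.random(n_cells) < 0.5, "pre", "post"), "post")
    else:
        tps = np.full(n_cells, "untreated")
    phen = np.array(PHENOTYPES)[clone_phen[clone_ix]]
    cytotox = np.isin(phen, list(CYTOTOXIC_PHENOTYPES))
    shifted = cytotox & (tps == "post") if treated else np.zeros(n_cells, bool)
    convert = shifted & (phen != "Prolif") & (
        rng.random(n_cells) < config.post_treatment_shift.prolif_conversion
    )
    phen = np.where(convert, "Prolif", phen)

    cells = pd.DataFrame({
        "cell_id": [f"{patient}_BC{i:06d}" for i in range(n_cells)],
        "patient_id": patient,
        "compartment": comp,
        "timepoint": tps,
        "lineage": np.array(LINEAGES)[clone_lin[clone_ix]],
        "phenotype": phen,
        "clone_id": clones["clone_id"].to_numpy()[clone_ix],
        "treatment_shifted": shifted,
    })
    return clones, cells


def _gene_panel(config: SimConfig) -> tuple[list[str], np.ndarray]:
    genes = list(MARKER_GENES) + list(MITO_GENES) + [
        f"BG{i + 1:03d}" for i in range(config.n_filler_genes)
    ]
    return genes, np.array(genes)


def _mean_matrix(config: SimConfig, cells: pd.DataFrame, genes: list[str],
                 rng: np.random.Generator) -> np.ndarray:
    """Per-cell NB mean vector from phenotype + treatment shift + mito state."""
    overrides = config.marker_means or _MARKER_OVERRIDES
    gene_index = {g: j for j, g in enumerate(genes)}
    phen_means = np.zeros((len(PHENOTYPES), len(genes)))
    for i, phen in enumerate(PHENOTYPES):
        row = np.zeros(len(genes))
        for g in MARKER_GENES:
            row[gene_index[g]] = _BASE_MARKER_MEAN
        for g in MITO_GENES:
            row[gene_index[g]] = _MITO_MEAN * (_MITO_PHENOTYPE_BOOST if phen == "Mito" else 1.0)
        for j in range(len(MARKER_GENES) + len(MITO_GENES), len(genes)):
            row[j] = config.filler_mean
        for g, m in overrides.get(phen, {}).items():
            row[gene_index[g]] = m
        phen_means[i] = row

    phen_idx = pd.Categorical(cells["phenotype"], categories=PHENOTYPES).codes
    means = phen_means[phen_idx].copy()

    shifted = cells["treatment_shifted"].to_numpy(dtype=bool)
    means[shifted, gene_index["MKI67"]] *= config.post_treatment_shift.mki67_multiplier
    means[shifted, gene_index["KLRG1"]] *= config.post_treatment_shift.klrg1_multiplier

    high_mito = rng.random(len(cells)) < config.high_mito_rate
    for g in MITO_GENES:
        means[high_mito, gene_index[g]] *= config.mito_boost
    return means


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, ad.AnnData, GroundTruth]:
    """Simulate cell metadata, a raw count matrix, and the ground truth.

    Returns (cells, adata, truth) where cells has one row per cell
    (cell_id, patient_id, compartment, timepoint, lineage, phenotype),
    adata holds raw marker-panel counts (cells x genes, sparse), and
    truth records the true clone of every cell and each clone's realized
    sharing status.
    """
    config.validate()
    used_cdr3: set[tuple[str, str]] = set()
    clone_frames, cell_frames = [], []
    for p_idx in range(config.n_patients):
        pc, cc = _simulate_patient(config, p_idx, used_cdr3)
        clone_frames.append(pc)
        cell_frames.append(cc)

    cells = pd.concat(cell_frames, ignore_index=True)
    clones = pd.concat(clone_frames, ignore_index=True).set_index("clone_id")
    clones["shared"] = (clones["n_blood"] > 0) & (clones["n_tumor"] > 0)

    genes, _ = _gene_panel(config)
    count_blocks = []
    for p_idx in range(config.n_patients):
        patient = f"P{p_idx + 1:02d}"
        rng = _patient_rng(config, p_idx, stream=1)
        sub = cells[cells["patient_id"] == patient]
        means = _mean_matrix(config, sub, genes, rng)
        lam = rng.gamma(config.nb_dispersion, means / config.nb_dispersion)
        count_blocks.append(rng.poisson(lam).astype(np.int32))
    counts = np.vstack(count_blocks)

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=cells.set_index("cell_id")[
            ["patient_id", "compartment", "timepoint", "lineage", "phenotype"]
        ].copy(),
        var=pd.DataFrame(
            {"is_mt": [g.startswith("MT-") for g in genes]},
            index=pd.Index(genes, name="gene"),
        ),
    )

    truth = GroundTruth(
        clones=clones,
        cell_to_clone=cells.set_index("cell_id")["clone_id"].rename("clone_id"),
    )
    cells = cells.drop(columns=["clone_id", "treatment_shifted"])
    return cells, adata, truth


def simulate_reads(cells: pd.DataFrame, truth: GroundTruth, config: SimConfig,
                   seed: int | None = None) -> pd.DataFrame:
    """Emit chain-level clonotype calls for every cell, with noise.

    Per chain: the true junction is dropped entirely with probability
    ``chain_dropout``; with probability ``tie_rate`` a decoy call with
    equal read count but strictly lower alignment score is added; with
    probability ``minor_call_rate`` an extra call with strictly lower
    read count is added.  The true call therefore always wins under the
    most-abundant / highest-score resolution rules when it is present.
    """
    rng = np.random.default_rng(config.seed + 977 if seed is None else seed)
    clone_ids = truth.cell_to_clone.loc[cells["cell_id"]].to_numpy()
    junctions = {
        "TRA": truth.clones.loc[clone_ids, "cdr3a"].to_numpy(),
        "TRB": truth.clones.loc[clone_ids, "cdr3b"].to_numpy(),
    }
    n = len(cells)
    records = []
    for locus in ("TRA", "TRB"):
        kept = rng.random(n) >= config.chain_dropout
        count = 1 + rng.poisson(4.0, size=n)
        score = np.round(rng.normal(90.0, 5.0, size=n), 2)
        idx = np.flatnonzero(kept)
        records.append(pd.DataFrame({
            "cell_id": cells["cell_id"].to_numpy()[idx],
            "locus": locus,
            "junction_aa": junctions[locus][idx],
            "duplicate_count": count[idx],
            "score": score[idx],
        }))
        # equal-abundance decoys, strictly lower alignment score
        tie = idx[rng.random(idx.size) < config.tie_rate]
        if tie.size:
            prefix = "CA" if locus == "TRA" else "CASS"
            decoys = [_random_cdr3(rng, prefix, "F") for _ in range(tie.size)]
            records.append(pd.DataFrame({
                "cell_id": cells["cell_id"].to_numpy()[tie],
                "locus": locus,
                "junction_aa": decoys,
                "duplicate_count": count[tie],
                "score": np.round(score[tie] - 0.5 - rng.exponential(3.0, tie.size), 2),
            }))
        # minor background calls, strictly lower read count
        minor = idx[(rng.random(idx.size) < config.minor_call_rate) & (count[idx] > 1)]
        if minor.size:
            prefix = "CA" if locus == "TRA" else "CASS"
            decoys = [_random_cdr3(rng, prefix, "F") for _ in range(minor.size)]
            records.append(pd.DataFrame({
                "cell_id": cells["cell_id"].to_numpy()[minor],
                "locus": locus,
                "junction_aa": decoys,
                "duplicate_count": rng.integers(1, count[minor]),
                "score": np.round(rng.normal(85.0, 5.0, minor.size), 2),
            }))
    calls = pd.concat(records, ignore_index=True)
    return calls.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


@dataclass
class RecoveryReport:
    matched_accuracy: float
    partition_ari: float
    per_phenotype: pd.DataFrame
    n_cells: int


def evaluate_recovery(labels: pd.DataFrame, truth: GroundTruth) -> RecoveryReport:
    """Compare pipeline labels with simulation ground truth.

    ``labels`` needs columns cell_id, patient_id, lineage, cluster_id,
    matched.  Raises ValueError if any labeled cell is unknown to the
    ground truth or the intersection is empty.
    """
    from sklearn.metrics import adjusted_rand_score

    ids = labels["cell_id"]
    known = ids.isin(truth.cell_to_clone.index)
    if not known.all():
        bad = ids[~known].head(5).tolist()
        raise ValueError(f"labels contain cell ids absent from ground truth: {bad}")
    if len(labels) == 0:
        raise ValueError("no overlapping cells between labels and ground truth")

    true_shared = truth.shared_flag_of_cells(ids)
    observed = labels["matched"].to_numpy(dtype=bool)
    accuracy = float((observed == true_shared).mean())

    true_clone = truth.cell_to_clone.loc[ids].to_numpy()
    observed_cluster = (
        labels["patient_id"].astype(str) + "/" + labels["lineage"].astype(str)
        + "/" + labels["cluster_id"].astype(str)
    ).to_numpy()
    ari = float(adjusted_rand_score(true_clone, observed_cluster))

    phen = truth.clones.loc[true_clone, "phenotype"].to_numpy()
    per_phen = (
        pd.DataFrame({"phenotype": phen, "observed_matched": observed, "true_shared": true_shared})
        .groupby("phenotype")
        .agg(n_cells=("observed_matched", "size"),
             observed_matched_frac=("observed_matched", "mean"),
             true_shared_frac=("true_shared", "mean"))
        .reset_index()
    )
    return RecoveryReport(
        matched_accuracy=accuracy,
        partition_ari=ari,
        per_phenotype=per_phen,
        n_cells=int(len(labels)),
    )
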