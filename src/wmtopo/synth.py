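"""Synthetic two-group connectome cohorts with known, recoverable effects.

Emulates the design of a case–control white-matter connectome study: two
groups of 30 subjects, 90 atlas nodes, one symmetric streamline-count
matrix per subject, and a clinical score table.  The generative model is:

* a **template** weighted graph shared by both groups: nodes sit on a ring,
  edge probability and edge weight decay with ring distance (a
  distance-penalized geometric graph, giving lattice-like clustering), and
  edges incident to a designated hub set are boosted (giving high-degree
  hubs and long-range shortcuts).  The resulting binary networks are
  small world across the 0.05–0.50 sparsity range;
* the **patient template** multiplies every edge weight incident to a
  designated anterior target-node set by ``1 - attenuation``;
* per-subject **streamline counts** are overdispersed (gamma–Poisson
  mixture, i.e. negative-binomial-like) draws with mean equal to the
  template weight; ``dispersion = inf`` recovers pure Poisson counts;
* **behavioral scores** follow the study's score battery; patients' frontal
  behavior inventory (FBI) subscales are linearly coupled to the nodal
  efficiency AUC of a designated target region (negative slope by default:
  lower efficiency, worse behavior), plus covariate effects and noise.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .atlas import AAL90_LABELS, indices
from .construct import ConstructionConfig, sweep_sparsity
from .metrics import auc_over_sparsity

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "StreamlineMatrix",
    "build_template",
    "sample_subject_matrix",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
    "subseed",
]

# the 7 "lost hub" regions plus the right superior orbitofrontal gyrus,
# the region whose efficiency couples to behavior
DEFAULT_TARGETS = indices(
    ["ACG.L", "INS.L", "HIP.L", "MTG.L", "ORBinf.R", "PreCG.R", "PUT.R", "ORBsup.R"]
)
# template high-degree regions: the targets' hub subset plus posterior hubs
DEFAULT_HUBS = indices(
    [
        "ACG.L", "INS.L", "HIP.L", "MTG.L", "ORBinf.R", "PreCG.R", "PUT.R",
        "PUT.L", "PCUN.L", "PCUN.R", "MOG.L", "LING.L", "LING.R", "DCG.R",
    ]
)

SCORE_NAMES = (
    "MMSE", "FTLD_CDR", "FBI_apathy", "FBI_disinhibition", "FBI_total",
    "TMT_A", "TMT_B", "Stroop_I", "Stroop_II", "BNT",
)

# (patient mean, patient sd, control mean, control sd) for the non-coupled
# scores, in the units of the usual clinical instruments
_SCORE_PARAMS = {
    "MMSE": (16.30, 5.17, 28.87, 1.59),
    "FTLD_CDR": (9.32, 2.95, 0.0, 0.0),
    "TMT_A": (105.81, 25.70, 52.97, 17.00),
    "TMT_B": (208.63, 65.02, 80.57, 31.96),
    "Stroop_I": (52.75, 20.62, 17.47, 4.02),
    "Stroop_II": (95.81, 41.65, 31.40, 6.25),
    "BNT": (17.10, 6.67, 26.07, 3.18),
}
# FBI subscale intercepts (patients) and near-floor control rates
_FBI_INTERCEPTS = {"FBI_apathy": 16.33, "FBI_disinhibition": 13.30}
_FBI_CONTROL_RATES = {"FBI_apathy": 0.17, "FBI_disinhibition": 0.07}


def subseed(seed: int, *tokens: str) -> np.random.Generator:
    """Generator for a named substream: stable across platforms and runs."""
    crcs = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([seed, *crcs]))


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the target study: two groups of 30, 90 AAL nodes,
    attenuated connectivity of an anterior target set in patients, and FBI
    subscales negatively coupled to the efficiency of the right superior
    orbitofrontal gyrus.
    """

    n_nodes: int = 90
    n_per_group: int = 30
    hub_nodes: tuple[int, ...] = DEFAULT_HUBS
    target_nodes: tuple[int, ...] = DEFAULT_TARGETS
    attenuation: float = 0.4
    base_density: float = 0.62
    count_scale: float = 60.0
    dispersion: float = 8.0
    score_coupling: float = -400.0
    score_noise_sd: float = 2.5
    covariate_effects: tuple[float, float, float] = (0.05, 0.5, -0.1)
    seed: int = 0
    # template shape parameters (not part of the study design proper)
    locality: float = 6.0
    hub_boost: float = 3.0
    hub_weight: float = 1.6
    backbone_weight: float = 6.0
    score_node: int | None = None  # default: last entry of target_nodes

    def __post_init__(self) -> None:
        if not (0.0 <= self.attenuation <= 1.0):
            raise ValueError("attenuation must lie in [0, 1]")
        if not (0.0 < self.base_density < 1.0):
            raise ValueError("base_density must lie in (0, 1)")
        if self.count_scale <= 0 or self.dispersion <= 0:
            raise ValueError("count_scale and dispersion must be positive")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")
        for name in ("hub_nodes", "target_nodes"):
            nodes = getattr(self, name)
            if any(not (0 <= v < self.n_nodes) for v in nodes):
                raise ValueError(f"{name} must be subsets of 0..n_nodes-1")

    @property
    def designated_score_node(self) -> int:
        if self.score_node is not None:
            return self.score_node
        return self.target_nodes[-1]

    def node_labels(self) -> tuple[str, ...]:
        if self.n_nodes == 90:
            return AAL90_LABELS
        return tuple(f"N{i:03d}" for i in range(self.n_nodes))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics and clinical scores."""

    id: str
    group: Literal["patient", "control"]
    age: float
    sex: Literal["M", "F"]
    education: float
    scores: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class StreamlineMatrix:
    """Symmetric nonnegative integer streamline-count matrix for one subject."""

    counts: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("counts must have a zero diagonal")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.node_labels) != c.shape[0]:
            raise ValueError("node_labels length must match matrix dimension")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# template and counts


def _ring_distance(n: int) -> np.ndarray:
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d).astype(float)


def build_template(config: CohortConfig, group: str) -> np.ndarray:
    """Weighted template matrix for one group.

    Both groups share the same base template (same seed); the patient
    template multiplies every weight incident to ``target_nodes`` by
    ``1 - attenuation``, so ``attenuation = 0`` makes the groups identical.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"group must be 'patient' or 'control', got {group!r}")
    n = config.n_nodes
    rng = subseed(config.seed, "template")
    d = _ring_distance(n)
    prox = np.exp(-d / config.locality)
    boost = np.ones((n, n))
    hubs = np.array(config.hub_nodes, dtype=int)
    if hubs.size:
        boost[hubs, :] *= config.hub_boost
        boost[:, hubs] *= config.hub_boost
        boost[np.ix_(hubs, hubs)] = config.hub_boost  # one endpoint is enough
    base = prox * boost
    np.fill_diagonal(base, 0.0)
    # scale edge probabilities (with cap at 1) to hit the requested density
    iu, ju = np.triu_indices(n, k=1)
    b = base[iu, ju]
    c = config.base_density * len(b) / b.sum()
    for _ in range(20):
        mean_p = np.minimum(1.0, c * b).mean()
        if abs(mean_p - config.base_density) < 1e-6:
            break
        c *= config.base_density / mean_p
    p = np.minimum(1.0, c * b)
    present = rng.random(len(b)) < p
    present |= d[iu, ju] == 1  # ring backbone: every node keeps its neighbors
    # graded weights: closer pairs carry more streamlines, with gamma noise;
    # hub-incident edges also carry more streamlines, so hubs keep elevated
    # degree at every sparsity, not just in the dense regime.  The ring
    # backbone shares the hub weight band so even the sparsest networks
    # retain a connected core (the study's admissible sparsity range).
    wfac = np.exp(-d[iu, ju] / (2.0 * config.locality))
    if hubs.size:
        hub_mask = np.zeros(n, dtype=bool)
        hub_mask[hubs] = True
        wfac = wfac * np.where(hub_mask[iu] | hub_mask[ju], config.hub_weight, 1.0)
    wfac = np.where(d[iu, ju] == 1, config.backbone_weight, wfac)
    noise = rng.gamma(shape=8.0, scale=0.125, size=len(b))
    w = np.where(present, config.count_scale * wfac * noise, 0.0)
    template = np.zeros((n, n))
    template[iu, ju] = w
    template += template.T
    if group == "patient" and config.attenuation > 0:
        mask = np.zeros(n, dtype=bool)
        mask[list(config.target_nodes)] = True
        incident = mask[:, None] | mask[None, :]
        template = np.where(incident, template * (1.0 - config.attenuation), template)
    return template


def sample_subject_matrix(
    template: np.ndarray,
    dispersion: float,
    seed: int | np.random.Generator,
    node_labels: tuple[str, ...] | None = None,
) -> StreamlineMatrix:
    """Overdispersed integer counts with mean equal to the template weight.

    Counts follow a gamma–Poisson mixture per upper-triangle entry:
    ``count ~ Poisson(Gamma(dispersion, mean/dispersion))``, which has mean
    ``mean`` and variance ``mean + mean^2/dispersion`` (negative-binomial
    form); ``dispersion = inf`` gives Poisson counts.  A zero template
    entry always yields count 0.
    """
    t = np.asarray(template, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or not np.allclose(t, t.T):
        raise ValueError("template must be square and symmetric")
    if np.any(t < 0):
        raise ValueError("template must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = t.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mu = t[iu, ju]
    if np.isinf(dispersion):
        lam = mu
    else:
        lam = np.where(mu > 0, rng.gamma(dispersion, mu / dispersion), 0.0)
    counts_u = rng.poisson(lam)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = counts_u
    counts += counts.T
    labels = node_labels or tuple(str(i) for i in range(n))
    return StreamlineMatrix(counts=counts, node_labels=labels)


# ---------------------------------------------------------------------------
# cohort


def _score_node_efficiency_auc(
    matrix: StreamlineMatrix, node: int, construction: ConstructionConfig
) -> float:
    """Nodal efficiency AUC of one node across the sparsity sweep."""
    nets = sweep_sparsity(matrix.counts, construction)
    effs = []
    for net in nets:
        d = dijkstra(csr_matrix(net.adjacency), unweighted=True, indices=node)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[node] = 0.0
        effs.append(inv.sum() / (net.n_nodes - 1))
    return auc_over_sparsity(effs, [net.sparsity for net in nets])


def generate_cohort(
    config: CohortConfig | None = None,
    construction: ConstructionConfig | None = None,
) -> list[tuple[SubjectRecord, StreamlineMatrix]]:
    """Generate the full two-group cohort: matrices plus clinical scores.

    Controls are listed first (ids ``HC…``), then patients (``PT…``).  Age,
    sex and education are drawn from identical distributions in both groups
    (matched design).  Patients' FBI subscales are
    ``intercept + score_coupling * (efficiency AUC − group mean) +
    covariate effects + noise``; the total is the exact subscale sum.
    """
    config = config or CohortConfig()
    construction = construction or ConstructionConfig()
    labels = config.node_labels()
    out: list[tuple[SubjectRecord, StreamlineMatrix]] = []
    score_effs: list[float] = []

    for group, prefix in (("control", "HC"), ("patient", "PT")):
        template = build_template(config, group)
        demo_rng = subseed(config.seed, "demographics", group)
        n = config.n_per_group
        ages = np.clip(demo_rng.normal(63.0, 6.5, size=n), 45.0, 85.0)
        edu = np.clip(demo_rng.normal(10.6, 3.5, size=n), 3.0, 22.0)
        # 13 M / 17 F per 30, scaled for other sizes, shuffled
        n_male = int(round(n * 13 / 30))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        demo_rng.shuffle(sexes)
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            mat = sample_subject_matrix(
                template, config.dispersion, subseed(config.seed, "matrix", sid), labels
            )
            rec = SubjectRecord(
                id=sid, group=group, age=float(ages[i]), sex=str(sexes[i]),
                education=float(edu[i]),
            )
            out.append((rec, mat))
            if group == "patient":
                score_effs.append(
                    _score_node_efficiency_auc(
                        mat, config.designated_score_node, construction
                    )
                )

    eff = np.asarray(score_effs)
    eff_centered = eff - eff.mean()
    b_age, b_sex, b_edu = config.covariate_effects
    finished: list[tuple[SubjectRecord, StreamlineMatrix]] = []
    pt_idx = 0
    for rec, mat in out:
        rng = subseed(config.seed, "scores", rec.id)
        scores: dict[str, float] = {}
        for name, (mp, sp, mc, sc) in _SCORE_PARAMS.items():
            if rec.group == "patient":
                v = rng.normal(mp, sp)
            else:
                v = rng.normal(mc, sc) if sc > 0 else mc
            scores[name] = float(max(v, 0.0))
        scores["MMSE"] = float(min(scores["MMSE"], 30.0))
        if rec.group == "patient":
            covar = (
                b_age * (rec.age - 63.0)
                + b_sex * (rec.sex == "M")
                + b_edu * (rec.education - 10.6)
            )
            for sub, intercept in _FBI_INTERCEPTS.items():
                v = (
                    intercept
                    + config.score_coupling * eff_centered[pt_idx]
                    + covar
                    + rng.normal(0.0, config.score_noise_sd)
                )
                scores[sub] = float(max(v, 0.0))
            pt_idx += 1
        else:
            for sub, rate in _FBI_CONTROL_RATES.items():
                scores[sub] = float(rng.poisson(rate))
        scores["FBI_total"] = scores["FBI_apathy"] + scores["FBI_disinhibition"]
        finished.append((replace(rec, scores=scores), mat))
    return finished


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(
    cohort: list[tuple[SubjectRecord, StreamlineMatrix]],
    outdir: str | Path,
    seed: int | None = None,
) -> Path:
    """Write matrices (TSV), node labels (TSV), metadata (CSV), manifest (JSON).

    Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    labels = cohort[0][1].node_labels
    with open(outdir / "node_labels.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for i, lab in enumerate(labels):
            w.writerow([i, lab])
    meta_path = outdir / "metadata.csv"
    with open(meta_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "group", "age", "sex", "education", *SCORE_NAMES])
        for rec, _ in cohort:
            w.writerow(
                [rec.id, rec.group, f"{rec.age:.2f}", rec.sex, f"{rec.education:.2f}"]
                + [f"{rec.scores[s]:.4f}" for s in SCORE_NAMES]
            )
    entries = []
    for rec, mat in cohort:
        rel = f"matrices/{rec.id}.tsv"
        np.savetxt(outdir / rel, mat.counts, fmt="%d", delimiter="\t")
        entries.append({"id": rec.id, "group": rec.group, "matrix": rel})
    manifest = {
        "n_nodes": len(labels),
        "seed": seed,
        "node_labels": "node_labels.tsv",
        "metadata": "metadata.csv",
        "subjects": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(manifest_path: str | Path) -> list[tuple[SubjectRecord, StreamlineMatrix]]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    labels: list[str] = []
    with open(root / manifest["node_labels"]) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            labels.append(row[1])
    meta: dict[str, dict[str, str]] = {}
    with open(root / manifest["metadata"]) as fh:
        for row in csv.DictReader(fh):
            meta[row["id"]] = row

    def num(raw: str | None) -> float:
        # blank or malformed cells become NaN; the validator flags them
        try:
            return float(raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return float("nan")

    out = []
    for entry in manifest["subjects"]:
        counts = np.loadtxt(root / entry["matrix"], delimiter="\t")
        m = meta[entry["id"]]
        rec = SubjectRecord(
            id=entry["id"], group=m["group"], age=num(m["age"]), sex=m["sex"],
            education=num(m["education"]),
            scores={s: num(m[s]) for s in SCORE_NAMES if s in m},
        )
        out.append((rec, StreamlineMatrix(counts=counts, node_labels=tuple(labels))))
    return out
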