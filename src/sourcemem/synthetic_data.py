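"""Ground-truth generators for cohorts, gaze streams, and isopter charts.

Every downstream stage — tabulation, Pr statistics, MPT fitting, the
hierarchical model, gaze QC, and perimetry — can be exercised offline
against data whose generating parameters are known exactly.

The default cohort emulates the study conditions: 25 young and 20 older
participants, 8 blocks, 80 test trials per tree (up-old / down-old / new)
per participant, responses drawn from the source-item MPT with
probit-normal individual variation around group means.  The default group
means echo the qualitative pattern of the findings — recollection of
upper-field positions reduced by about 0.2 in the older group, familiarity
similar, a slightly lower old-guessing rate in the older group — without
claiming to match any fitted values.  Misses are independent Bernoulli
events per trial.  Reaction-time fields are filled with placeholder
lognormal draws and are not analysed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gaze_qc import StabilityCategory
from .mpt_model import MPTParams, PARAM_NAMES, category_probabilities_array
from .perimetry_vma import Eye, IsopterChart, IsopterLabel, chart_vma
from .task_data import (Group, ItemResponse, Position, SourceResponse,
                        TrialRecord, TREES)
from .hierarchical_mpt import probit, inverse_probit

__all__ = [
    "DEFAULT_GROUP_MEANS",
    "CohortSpec",
    "GroundTruth",
    "gen_cohort",
    "gen_gaze",
    "gen_isopters",
]

DEFAULT_GROUP_MEANS: dict[Group, MPTParams] = {
    Group.YOUNG: MPTParams(s_up=0.50, s_down=0.55, i_up=0.50, i_down=0.55,
                           o=0.45, g=0.50),
    Group.OLDER: MPTParams(s_up=0.30, s_down=0.45, i_up=0.45, i_down=0.45,
                           o=0.38, g=0.45),
}


@dataclass
class CohortSpec:
    """Generating conditions for a synthetic two-group cohort."""

    n_young: int = 25
    n_older: int = 20
    trials_per_tree: int = 80
    n_blocks: int = 8
    group_means: dict[Group, MPTParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    latent_sd: np.ndarray = field(
        default_factory=lambda: np.full(6, 0.3))  # probit-scale SD per parameter
    latent_corr: np.ndarray = field(default_factory=lambda: np.eye(6))
    miss_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_young < 1 or self.n_older < 1:
            raise ValueError("each group needs at least one participant")
        self.latent_sd = np.asarray(self.latent_sd, dtype=float)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.latent_sd.shape != (6,):
            raise ValueError("latent_sd must have length 6")
        if self.latent_corr.shape != (6, 6):
            raise ValueError("latent_corr must be 6x6")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise ValueError("latent_corr must be symmetric")
        eigvals = np.linalg.eigvalsh(self.latent_corr)
        if eigvals.min() <= 0:
            raise ValueError("latent_corr must be positive definite")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must be in [0, 1)")

    @property
    def covariance(self) -> np.ndarray:
        return self.latent_corr * np.outer(self.latent_sd, self.latent_sd)


@dataclass
class GroundTruth:
    """Generating parameters retained alongside a synthetic cohort."""

    seed: int
    params: dict[str, MPTParams]             # per participant
    groups: dict[str, Group]
    counts: dict[str, np.ndarray]            # realised 3x3 answered-response counts
    miss_counts: dict[str, np.ndarray]       # per-tree missed trials

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "participants": {
                pid: {
                    "group": self.groups[pid].value,
                    "params": self.params[pid].as_dict(),
                    "counts": self.counts[pid].tolist(),
                    "miss_counts": self.miss_counts[pid].tolist(),
                }
                for pid in self.params
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        parts = payload["participants"]
        return cls(
            seed=payload["seed"],
            params={p: MPTParams(**{k.lower(): v for k, v in d["params"].items()})
                    for p, d in parts.items()},
            groups={p: Group(d["group"]) for p, d in parts.items()},
            counts={p: np.array(d["counts"]) for p, d in parts.items()},
            miss_counts={p: np.array(d["miss_counts"]) for p, d in parts.items()},
        )


_CATEGORY_RESPONSES = (
    (ItemResponse.OLD, SourceResponse.UP),
    (ItemResponse.OLD, SourceResponse.DOWN),
    (ItemResponse.NEW, SourceResponse.NONE),
)


def gen_cohort(spec: CohortSpec) -> tuple[list[TrialRecord], GroundTruth]:
    """Simulate a two-group cohort of trial records with known ground truth.

    Per participant: a probit-scale latent vector is drawn from the group
    multivariate normal and transformed to MPT probabilities; per tree,
    ``trials_per_tree`` categorical outcomes are drawn from the category
    probabilities; an independent Bernoulli miss process overwrites
    responses; trials are spread as evenly as possible over the blocks.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.covariance
    chol = np.linalg.cholesky(cov) if spec.latent_sd.max() > 0 else np.zeros((6, 6))

    trials: list[TrialRecord] = []
    gt_params: dict[str, MPTParams] = {}
    gt_groups: dict[str, Group] = {}
    gt_counts: dict[str, np.ndarray] = {}
    gt_miss: dict[str, np.ndarray] = {}

    roster = ([(Group.YOUNG, i) for i in range(spec.n_young)]
              + [(Group.OLDER, i) for i in range(spec.n_older)])
    for group, i in roster:
        pid = f"{group.value[0].upper()}{i + 1:03d}"
        mean_probit = probit(spec.group_means[group].as_array())
        z = mean_probit + chol @ rng.standard_normal(6)
        theta = np.clip(inverse_probit(z), 1e-6, 1 - 1e-6)
        params = MPTParams.from_array(theta)
        probs = category_probabilities_array(theta)  # (3, 3)

        counts = np.zeros((3, 3), dtype=int)
        misses = np.zeros(3, dtype=int)
        # per-trial category draws, then block assignment round-robin
        per_block = spec.trials_per_tree // spec.n_blocks
        extra = spec.trials_per_tree % spec.n_blocks
        for ti, tree in enumerate(TREES):
            cats = rng.choice(3, size=spec.trials_per_tree, p=probs[ti])
            missed = rng.random(spec.trials_per_tree) < spec.miss_rate
            k = 0
            for b in range(spec.n_blocks):
                n_b = per_block + (1 if b < extra else 0)
                for _ in range(n_b):
                    cat, is_miss = cats[k], missed[k]
                    k += 1
                    item_id = f"{pid}-{tree.value}-{k:03d}"
                    if is_miss:
                        misses[ti] += 1
                        trials.append(TrialRecord(
                            pid, group, b + 1, item_id, tree,
                            ItemResponse.MISS, SourceResponse.NONE))
                        continue
                    counts[ti, cat] += 1
                    item_resp, src_resp = _CATEGORY_RESPONSES[cat]
                    rt_item = float(rng.lognormal(-0.3, 0.4))
                    rt_source = (float(rng.lognormal(-0.2, 0.4))
                                 if item_resp == ItemResponse.OLD else None)
                    trials.append(TrialRecord(
                        pid, group, b + 1, item_id, tree, item_resp, src_resp,
                        rt_item=rt_item, rt_source=rt_source))
        gt_params[pid] = params
        gt_groups[pid] = group
        gt_counts[pid] = counts
        gt_miss[pid] = misses

    return trials, GroundTruth(spec.seed, gt_params, gt_groups, gt_counts, gt_miss)


# ---------------------------------------------------------------------------
# gaze streams

_FIXATION_TARGETS = {
    # offsets (degrees from center) cycled over successive fixation epochs;
    # chosen so default QC settings reproduce the requested Fujii category even
    # if adjacent epochs merge (any average of neighbouring targets stays in
    # the intended annulus)
    StabilityCategory.STABLE: [(0.0, 0.0)],
    # all epochs at 3 degrees: 0% inside 2, 100% inside 4
    StabilityCategory.RELATIVELY_UNSTABLE: [(0.0, 3.0), (3.0, 0.0), (0.0, -3.0), (-3.0, 0.0)],
    # all epochs beyond 4 degrees: unstable, excluded
    StabilityCategory.UNSTABLE: [(6.0, 0.0), (0.0, 6.0), (-6.0, 0.0), (0.0, -6.0)],
}


def gen_gaze(stability: StabilityCategory, duration_s: float, seed: int = 0,
             center: tuple[float, float] = (0.0, 0.0), jitter_sd: float = 0.05,
             rate_hz: float = 1000.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a 1000-Hz gaze stream of the requested stability category.

    Returns (t_ms, x_deg, y_deg).  The stream is a cycle of ~400-ms fixation
    epochs at category-specific offsets with Gaussian jitter, joined by 20-ms
    saccadic ramps.  Under default :mod:`sourcemem.gaze_qc` settings the
    resulting centroids classify into the requested category.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    stability = StabilityCategory(stability)
    rng = np.random.default_rng(seed)
    dt = 1000.0 / rate_hz
    n = int(round(duration_s * 1000.0 / dt))
    targets = _FIXATION_TARGETS[stability]
    epoch_ms, saccade_ms = 400.0, 20.0
    epoch_n = int(epoch_ms / dt)
    sacc_n = max(int(saccade_ms / dt), 1)

    xs = np.empty(n)
    ys = np.empty(n)
    i = 0
    ep = 0
    cur = targets[0]
    while i < n:
        tx, ty = targets[ep % len(targets)]
        if ep > 0:
            # saccadic ramp from previous target
            m = min(sacc_n, n - i)
            frac = np.linspace(0, 1, m, endpoint=False)
            xs[i:i + m] = cur[0] + (tx - cur[0]) * frac
            ys[i:i + m] = cur[1] + (ty - cur[1]) * frac
            i += m
        m = min(epoch_n, n - i)
        xs[i:i + m] = tx + rng.normal(0, jitter_sd, m)
        ys[i:i + m] = ty + rng.normal(0, jitter_sd, m)
        i += m
        cur = (tx, ty)
        ep += 1
    t = np.arange(n) * dt
    return t, xs + center[0], ys + center[1]


# ---------------------------------------------------------------------------
# isopter charts

def gen_isopters(target_vma: float, base_radius: float = 45.0, seed: int = 0,
                 n_points: int = 36, noise_frac: float = 0.02,
                 eye: Eye = Eye.RIGHT,
                 isopter: IsopterLabel = IsopterLabel.III1E) -> IsopterChart:
    """Generate an isopter whose polygonal VMA is within 1 of ``target_vma``.

    Upper and lower radii are scaled so the hemifield area ratio yields the
    target asymmetry; small multiplicative radius noise emulates charting
    variability, and a short fixed-point calibration rescales the lower
    hemifield to land the realised (polygonal) VMA on target.
    """
    if not abs(target_vma) < 200:
        raise ValueError("target VMA must lie strictly inside (-200, 200)")
    rng = np.random.default_rng(seed)
    v = target_vma / 100.0
    # lower^2 / upper^2 ratio giving the target on exact half-discs
    rho = (2.0 + v) / (2.0 - v)
    r_upper = base_radius
    r_lower = base_radius * np.sqrt(rho)

    angles = np.arange(n_points) * (360.0 / n_points)
    noise = 1.0 + rng.normal(0.0, noise_frac, n_points)

    def build(scale_lower: float) -> IsopterChart:
        radii = np.where(np.sin(np.deg2rad(angles)) > 0, r_upper,
                         np.where(np.sin(np.deg2rad(angles)) < 0,
                                  r_lower * scale_lower,
                                  (r_upper + r_lower * scale_lower) / 2))
        return IsopterChart(eye, isopter, np.column_stack([angles, radii * noise]))

    scale = 1.0
    chart = build(scale)
    for _ in range(20):
        res = chart_vma(chart)
        if res.vma is not None and abs(res.vma - target_vma) <= 0.05:
            break
        # adjust the lower/upper area ratio toward the target
        cur_v = res.vma / 100.0
        ratio_cur = (2.0 + cur_v) / (2.0 - cur_v)
        ratio_tgt = (2.0 + v) / (2.0 - v)
        scale *= np.sqrt(ratio_tgt / ratio_cur)
        chart = build(scale)
    else:
        raise RuntimeError("isopter calibration failed to reach target VMA")
    return chart
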