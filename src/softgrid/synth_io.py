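"""Synthetic observer scores, score/image I/O, and study-design arithmetic.

No raw observer scores from the motivating study design are available, so the
generator emulates them: an ordinal-probit model in which each response's
latent quality is the sum of an image effect, an observer effect, a
per-question treatment-arm effect, and fresh observation noise, cut into the
five agreement categories by fixed thresholds.  The Gaussian latent scale
makes the cross-pair win probability — and hence the expected AUC_VGC — a
closed form, which the tests use as an exact oracle.

The default :class:`StudyDesign` mirrors a paired reading study: 30 image
pairs read in both arms by six observers (two ITU consultants, two ITU
registrars, one radiology consultant, one radiology registrar), supplemented
by four duplicate reviews per arm for consistency analysis, i.e. 68 reviews
per observer, each answering six questions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phantom_forward import AcquisitionConfig, RawImage, exposure_index
from .vgc_stats import ARMS, QUESTIONS, ROLES

__all__ = [
    "StudyDesign",
    "EffectModel",
    "generate_scores",
    "expected_auc",
    "read_scores",
    "write_scores",
    "read_image",
    "write_image",
    "elimination_arithmetic",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = (
    "observer_id",
    "role",
    "image_id",
    "arm",
    "question",
    "score",
    "review_order",
)

DEFAULT_OBSERVERS: tuple[tuple[str, str], ...] = (
    ("obs1", "itu_consultant"),
    ("obs2", "itu_consultant"),
    ("obs3", "itu_registrar"),
    ("obs4", "itu_registrar"),
    ("obs5", "radiology_consultant"),
    ("obs6", "radiology_registrar"),
)


@dataclass
class StudyDesign:
    """Reading-study layout: who reviews what, how often."""

    n_images: int = 30
    n_duplicates: int = 4  # duplicated reviews per arm per observer
    observers: tuple[tuple[str, str], ...] = DEFAULT_OBSERVERS
    questions: tuple[str, ...] = QUESTIONS
    na_probability: float = 2.0 / 2448.0
    # whether the duplicated cases are the same images in both arms (paired
    # duplicates) or distinct cases per arm
    duplicates_same_cases: bool = False

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.n_duplicates < 0:
            raise ValueError("need n_images >= 1 and n_duplicates >= 0")
        if not (0.0 <= self.na_probability < 1.0):
            raise ValueError("na_probability must be in [0, 1)")
        for _, role in self.observers:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")

    @property
    def images_per_observer(self) -> int:
        return 2 * self.n_images + 2 * self.n_duplicates

    @property
    def total_responses(self) -> int:
        return len(self.observers) * self.images_per_observer * len(self.questions)


@dataclass
class EffectModel:
    """Ordinal-probit score model on a Gaussian latent quality scale."""

    delta: dict[str, float] = field(default_factory=dict)  # per-question arm effect
    image_sd: float = 0.7
    observer_sd: float = 0.3
    noise_sd: float = 0.6
    thresholds: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in (self.image_sd, self.observer_sd, self.noise_sd)):
            raise ValueError("standard deviations must be non-negative")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def delta_for(self, question: str) -> float:
        return float(self.delta.get(question, 0.0))


def generate_scores(design: StudyDesign, model: EffectModel) -> pd.DataFrame:
    """Draw a full long-format score table for the given design and model.

    Latent quality per response:
    ``image_effect + observer_effect + delta_q * [arm == TRUEVIEW] + noise``;
    the score is 1 plus the number of thresholds below the latent value.
    Review order is an independent random permutation per observer (blind,
    randomized presentation); duplicates share the image effect but redraw
    the observation noise; N/A responses are injected at ``na_probability``.
    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    nq = len(design.questions)
    image_ids = [f"img{i:03d}" for i in range(design.n_images)]
    # per-(image, question) random effect, shared by both arms and duplicates
    img_eff = rng.normal(0.0, model.image_sd, size=(design.n_images, nq))
    obs_eff = rng.normal(0.0, model.observer_sd, size=len(design.observers))
    thresholds = np.asarray(model.thresholds)

    rows: list[dict] = []
    for oi, (obs_id, role) in enumerate(design.observers):
        # reading list: every image once per arm, plus duplicates
        reviews: list[tuple[int, str]] = [
            (i, arm) for i in range(design.n_images) for arm in ARMS
        ]
        if design.n_duplicates > 0:
            if design.duplicates_same_cases:
                dup = rng.choice(design.n_images, design.n_duplicates, replace=False)
                dup_oem = dup_tv = dup
            else:
                dup = rng.choice(
                    design.n_images, 2 * design.n_duplicates, replace=False
                )
                dup_oem, dup_tv = dup[: design.n_duplicates], dup[design.n_duplicates :]
            reviews += [(int(i), "OEM") for i in dup_oem]
            reviews += [(int(i), "TRUEVIEW") for i in dup_tv]
        order = rng.permutation(len(reviews)) + 1
        for (img, arm), pos in zip(reviews, order):
            for qi, q in enumerate(design.questions):
                latent = (
                    img_eff[img, qi]
                    + obs_eff[oi]
                    + model.delta_for(q) * (arm == "TRUEVIEW")
                    + rng.normal(0.0, model.noise_sd)
                )
                score: float | None = 1.0 + float(np.sum(latent > thresholds))
                if design.na_probability > 0 and rng.random() < design.na_probability:
                    score = None
                rows.append(
                    dict(
                        observer_id=obs_id,
                        role=role,
                        image_id=image_ids[img],
                        arm=arm,
                        question=q,
                        score=score,
                        review_order=int(pos),
                    )
                )
    table = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    table["score"] = table["score"].astype(float)
    return table


def expected_auc(model: EffectModel, question: str) -> float:
    """Closed-form expected AUC_VGC under the ordinal-probit model.

    For independent draws of one arm-a and one arm-b score, the category
    probabilities are increments of Phi((c_k - delta_arm)/sigma_tot) with
    sigma_tot^2 the sum of all variance components; the AUC is the
    tie-corrected cross-pair win probability of those two categoricals.
    """
    sigma = math.sqrt(
        model.image_sd**2 + model.observer_sd**2 + model.noise_sd**2
    )
    if sigma == 0:
        raise ValueError("degenerate latent scale")
    c = np.asarray(model.thresholds, dtype=float)

    def cat_probs(delta: float) -> np.ndarray:
        cdf = norm.cdf((c - delta) / sigma)
        return np.diff(np.concatenate([[0.0], cdf, [1.0]]))

    p_oem = cat_probs(0.0)
    p_tv = cat_probs(model.delta_for(question))
    wins = sum(
        p_tv[i] * p_oem[j] for i in range(5) for j in range(5) if i > j
    )
    ties = float((p_tv * p_oem).sum())
    return wins + 0.5 * ties


# ---------------------------------------------------------------------------
# Score CSV I/O
# ---------------------------------------------------------------------------

def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format score CSV (missing scores as literal ``NA``)."""
    out = table.loc[:, list(SCORE_COLUMNS)].copy()
    out["score"] = out["score"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:g}"
    )
    out.to_csv(path, index=False)


class ScoreSchemaError(ValueError):
    """A score CSV row violates the schema; the message names the row."""


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format score CSV.

    Schema violations are rejected with 1-based data-row numbers in the
    message.  The ``NA`` literal marks missing scores; ``review_order`` must
    be a positive integer, unique per observer.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SCORE_COLUMNS) - set(table.columns)
    if missing:
        raise ScoreSchemaError(f"missing columns: {sorted(missing)}")

    def bad(i: int, msg: str) -> ScoreSchemaError:
        return ScoreSchemaError(f"row {i + 1}: {msg}")

    scores: list[float] = []
    orders: list[int] = []
    for i, row in table.iterrows():
        if row["role"] not in ROLES:
            raise bad(i, f"unknown role {row['role']!r}")
        if row["arm"] not in ARMS:
            raise bad(i, f"unknown arm {row['arm']!r}")
        if row["question"] not in QUESTIONS:
            raise bad(i, f"unknown question {row['question']!r}")
        s = row["score"]
        if s == "NA":
            scores.append(np.nan)
        else:
            try:
                v = float(s)
            except ValueError:
                raise bad(i, f"unparseable score {s!r}") from None
            if not (1.0 <= v <= 5.0) or v != int(v):
                raise bad(i, f"score {s!r} not an integer in 1..5 or NA")
            scores.append(v)
        try:
            o = int(row["review_order"])
        except ValueError:
            raise bad(i, f"unparseable review_order {row['review_order']!r}") from None
        if o < 1:
            raise bad(i, f"review_order {o} not positive")
        orders.append(o)

    table = table.assign(score=scores, review_order=orders)
    # review order must be unique within an observer (each review has a slot)
    per = table.drop_duplicates(["observer_id", "image_id", "arm", "review_order"])
    dup = per.duplicated(["observer_id", "review_order"])
    if dup.any():
        raise ScoreSchemaError(
            f"duplicate review_order within observer at data row {int(dup.idxmax()) + 1}"
        )
    return table


# ---------------------------------------------------------------------------
# Image I/O (16-bit PNG / float TIFF with a JSON metadata sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: RawImage, path: str | Path) -> None:
    """Write a raw image plus a JSON sidecar with acquisition metadata.

    ``.tif``/``.tiff`` stores float32 counts (lossless for detector counts);
    ``.png`` stores 16-bit unsigned with values clipped to [0, 65535].
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.intensity.astype(np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        if image.intensity.max() > 65535:
            warnings.warn("intensities above 65535 clipped for 16-bit PNG")
        iio.imwrite(
            path, np.clip(np.rint(image.intensity), 0, 65535).astype(np.uint16)
        )
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    cfg = image.config
    meta = dict(
        kvp=cfg.kvp,
        mas=cfg.mas,
        i0=cfg.i0,
        sid_cm=cfg.sid_cm,
        detector_gain=cfg.detector_gain,
        pixel_pitch_mm=cfg.pixel_pitch_mm,
        seed=cfg.seed,
        exposure_index=image.exposure_index,
    )
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> RawImage:
    """Read a raw image; missing sidecar metadata falls back to defaults
    (with a warning), since the solver needs kVp/mAs/I0 to run at all."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        ei = meta.pop("exposure_index", None)
        cfg = AcquisitionConfig(**meta)
    else:
        warnings.warn(f"no metadata sidecar for {path.name}; using defaults")
        cfg = AcquisitionConfig()
        ei = None
    if ei is None:
        ei = exposure_index(arr, cfg)
    return RawImage(intensity=arr, config=cfg, exposure_index=float(ei))


# ---------------------------------------------------------------------------
# Study-design arithmetic
# ---------------------------------------------------------------------------

def elimination_arithmetic(stages: list[int], n_start: int) -> int:
    """Sequential image-elimination bookkeeping: n_start minus each stage.

    Raises if any intermediate count would go negative (over-elimination).
    """
    n = int(n_start)
    for k, stage in enumerate(stages, start=1):
        n -= int(stage)
        if n < 0:
            raise ValueError(f"elimination stage {k} leaves a negative count")
    return n
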