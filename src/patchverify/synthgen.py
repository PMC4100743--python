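"""Reproducible synthetic disguised-face datasets with ground truth.

Subjects are procedural textures, not rendered faces: each subject gets a
deterministic base appearance made of a smooth low-frequency "skin" field
plus a subject-specific mid-frequency texture signature. The matching
method only ever sees per-patch histograms, so a stable texture identity
is exactly what it needs; this keeps the repository image-free and
license-free. Disguise accessories overwrite rectangular footprints with
either a near-uniform dark fill ("sunglasses/scarf"-like) or
high-variance noise ("wig/beard"-like), and every image carries a
per-pixel coverage map from which the patch annotations are recomputed:
a patch is non-biometric iff strictly more than half of its pixels are
covered.

All randomness flows from a single spec seed through named substreams
(subjects, per-image rendering, accessory choice and jitter, splits), so
a rerun with the same spec is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .faceio import DEFAULT_GRID, NormalizedFace, PatchGrid, write_image, write_manifest
from .patch_classifier import BIOMETRIC, NON_BIOMETRIC

__all__ = [
    "AccessorySpec",
    "SyntheticSpec",
    "SyntheticImage",
    "SyntheticDataset",
    "ACCESSORY_KINDS",
    "default_accessory_pool",
    "make_subject_prototype",
    "apply_accessory",
    "annotate",
    "coverage_fractions",
    "generate_dataset",
    "gallery_probe_split",
    "write_dataset",
    "load_dataset",
]

ACCESSORY_KINDS = (
    "sunglasses_like",
    "scarf_like",
    "wig_like",
    "beard_like",
    "cap_like",
    "mask_like",
)

# footprint rows of the default 5-row grid each accessory occupies
_KIND_ROWS = {
    "sunglasses_like": (1, 2),
    "scarf_like": (3, 5),
    "wig_like": (0, 1),
    "beard_like": (4, 5),
    "cap_like": (0, 1),
    "mask_like": (2, 4),
}
_KIND_APPEARANCE = {
    "sunglasses_like": "uniform_dark",
    "scarf_like": "uniform_dark",
    "wig_like": "high_texture_noise",
    "beard_like": "high_texture_noise",
    "cap_like": "uniform_dark",
    "mask_like": "uniform_dark",
}


@dataclasses.dataclass(frozen=True)
class AccessorySpec:
    """A disguise accessory: a rectangular footprint plus an appearance.

    ``footprint`` is (row0, col0, row1, col1) in pixels, half-open, in
    canonical face coordinates. ``appearance`` is "uniform_dark" (constant
    ``dark_value`` plus a little sensor noise) or "high_texture_noise"
    (uniform noise of high variance).
    """

    kind: str
    footprint: tuple[int, int, int, int]
    appearance: str
    dark_value: int = 18
    noise_sigma: float = 4.0

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.footprint
        if not (0 <= r0 < r1 and 0 <= c0 < c1):
            raise ValueError(f"degenerate footprint {self.footprint}")
        if self.appearance not in ("uniform_dark", "high_texture_noise"):
            raise ValueError(f"unknown appearance {self.appearance!r}")


def default_accessory_pool(grid: PatchGrid = DEFAULT_GRID) -> list[AccessorySpec]:
    """One accessory per kind, footprints aligned to grid rows."""
    pool = []
    for kind in ACCESSORY_KINDS:
        row0, row1 = _KIND_ROWS[kind]
        pool.append(
            AccessorySpec(
                kind=kind,
                footprint=(
                    row0 * grid.patch_height,
                    0,
                    row1 * grid.patch_height,
                    grid.face_width,
                ),
                appearance=_KIND_APPEARANCE[kind],
            )
        )
    return pool


@dataclasses.dataclass
class SyntheticSpec:
    """Study-design parameters of a generated dataset.

    Defaults reproduce the reference composition: 75 subjects split 35
    train / 40 test, 6-10 images each (at least 1 neutral and 5
    disguised), 322 train and 359 test images in total. When the image
    totals are None, per-subject counts are drawn uniformly from the
    range instead.
    """

    n_subjects: int = 75
    train_subjects: int = 35
    images_per_subject: tuple[int, int] = (6, 10)
    neutral_per_subject: int = 1
    disguised_per_subject: int = 5
    train_total_images: int | None = 322
    test_total_images: int | None = 359
    accessory_jitter: int = 3
    seed: int = 0
    grid: PatchGrid = dataclasses.field(default_factory=PatchGrid)

    def __post_init__(self) -> None:
        lo, hi = self.images_per_subject
        if not (0 < lo <= hi):
            raise ValueError("images_per_subject range must be positive")
        if self.neutral_per_subject < 1 or self.disguised_per_subject < 1:
            raise ValueError("need at least one neutral and one disguised image")
        if self.neutral_per_subject + self.disguised_per_subject > lo:
            raise ValueError(
                "neutral_per_subject + disguised_per_subject exceeds the "
                "minimum images per subject"
            )
        if not 0 < self.train_subjects < self.n_subjects:
            raise ValueError("train_subjects must split the subject pool")
        for total, count in (
            (self.train_total_images, self.train_subjects),
            (self.test_total_images, self.n_subjects - self.train_subjects),
        ):
            if total is not None and not (count * lo <= total <= count * hi):
                raise ValueError(
                    f"total {total} infeasible for {count} subjects with "
                    f"{lo}-{hi} images each"
                )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclasses.dataclass
class SyntheticImage:
    face: NormalizedFace
    coverage: np.ndarray          # per-pixel accessory coverage in [0, 1]
    annotation: np.ndarray        # (m, n) label strings, recomputable from coverage
    accessories: tuple[str, ...]  # kinds applied
    split: str                    # "train" | "test"

    @property
    def image_id(self) -> str:
        return self.face.image_id

    @property
    def subject_id(self) -> str:
        return self.face.subject_id


@dataclasses.dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    images: list[SyntheticImage]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [im.image_id for im in self.images],
                "subject_id": [im.subject_id for im in self.images],
                "path": [f"images/{im.image_id}.pgm" for im in self.images],
                "is_neutral": [im.face.is_neutral for im in self.images],
                "split": [im.split for im in self.images],
            }
        )

    def split_images(self, split: str) -> list[SyntheticImage]:
        return [im for im in self.images if im.split == split]


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def make_subject_prototype(
    subject_seed: int,
    grid: PatchGrid = DEFAULT_GRID,
) -> NormalizedFace:
    """Deterministic per-subject base appearance.

    Smooth low-frequency "skin" illumination field plus a mid-frequency
    texture signature unique to the seed; distinct seeds give textures
    whose LBP statistics differ by far more than the per-image render
    noise added later.
    """
    rng = _substream(subject_seed, 0)
    h, w = grid.face_height, grid.face_width
    skin = gaussian_filter(rng.normal(size=(h, w)), sigma=18)
    skin = skin / (np.abs(skin).max() + 1e-12)
    texture = gaussian_filter(rng.normal(size=(h, w)), sigma=1.6)
    texture = texture / texture.std()
    base = 128 + 45 * skin + 22 * texture
    return NormalizedFace(np.clip(np.rint(base), 0, 255).astype(np.uint8))


def apply_accessory(
    face: NormalizedFace,
    acc: AccessorySpec,
    jitter_seed: int = 0,
    *,
    jitter: int = 0,
) -> tuple[NormalizedFace, np.ndarray]:
    """Overlay one accessory; returns (new face, per-pixel coverage map).

    ``jitter`` shifts the footprint by a seeded offset drawn uniformly in
    [-jitter, jitter] per axis, clipped to the frame.
    """
    h, w = face.pixels.shape
    r0, c0, r1, c1 = acc.footprint
    if r1 > h or c1 > w:
        raise ValueError(f"footprint {acc.footprint} outside {w}x{h} frame")
    rng = _substream(jitter_seed, 1)
    if jitter > 0:
        dr = int(rng.integers(-jitter, jitter + 1))
        dc = int(rng.integers(-jitter, jitter + 1))
    else:
        dr = dc = 0
    r0, r1 = np.clip([r0 + dr, r1 + dr], 0, h)
    c0, c1 = np.clip([c0 + dc, c1 + dc], 0, w)
    pixels = face.pixels.astype(float).copy()
    coverage = np.zeros((h, w))
    if r1 > r0 and c1 > c0:
        shape = (r1 - r0, c1 - c0)
        if acc.appearance == "uniform_dark":
            fill = acc.dark_value + rng.normal(scale=acc.noise_sigma, size=shape)
        else:
            fill = rng.uniform(0, 255, size=shape)
        pixels[r0:r1, c0:c1] = fill
        coverage[r0:r1, c0:c1] = 1.0
    out = NormalizedFace(
        np.clip(np.rint(pixels), 0, 255).astype(np.uint8),
        subject_id=face.subject_id,
        is_neutral=False,
        image_id=face.image_id,
    )
    return out, coverage


def annotate(coverage: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """(m, n) patch labels: non-biometric iff mean coverage > 0.5 strictly."""
    frac = coverage_fractions(coverage, grid)
    return np.where(frac > 0.5, NON_BIOMETRIC, BIOMETRIC)


def coverage_fractions(coverage: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """(m, n) per-patch mean pixel coverage."""
    coverage = np.asarray(coverage, dtype=float)
    if coverage.shape != (grid.face_height, grid.face_width):
        raise ValueError("coverage map does not match grid geometry")
    if coverage.min() < 0 or coverage.max() > 1:
        raise ValueError("coverage values must lie in [0, 1]")
    out = np.empty((grid.m, grid.n))
    for i in range(grid.m):
        for j in range(grid.n):
            rs, cs = grid.bounds(i, j)
            out[i, j] = coverage[rs, cs].mean()
    return out


def _allocate_counts(
    rng: np.random.Generator, n: int, lo: int, hi: int, total: int | None
) -> np.ndarray:
    """Per-subject image counts in [lo, hi], summing to ``total`` if given."""
    if total is None:
        return rng.integers(lo, hi + 1, size=n)
    counts = np.full(n, lo)
    remaining = total - n * lo
    while remaining > 0:
        open_idx = np.flatnonzero(counts < hi)
        take = min(remaining, open_idx.size)
        chosen = rng.choice(open_idx, size=take, replace=False)
        counts[chosen] += 1
        remaining -= take
    return counts


def _render_image(
    proto: NormalizedFace, rng: np.random.Generator
) -> np.ndarray:
    """Per-image render: small illumination gain/offset plus sensor noise."""
    gain = rng.normal(1.0, 0.04)
    offset = rng.normal(0.0, 5.0)
    noise = rng.normal(0.0, 3.0, size=proto.pixels.shape)
    out = proto.pixels.astype(float) * gain + offset + noise
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate images, coverage maps, annotations and the subject split.

    Subjects are shuffled with a seeded stream and the first
    ``train_subjects`` go to the train split. Each subject gets at least
    ``neutral_per_subject`` neutral and ``disguised_per_subject``
    disguised images; extras are disguised with probability 0.75. Each
    disguised image carries one or two accessories of distinct kinds.
    """
    grid = spec.grid
    pool = default_accessory_pool(grid)
    split_rng = _substream(spec.seed, 100)
    order = split_rng.permutation(spec.n_subjects)
    split_of = {
        int(s): ("train" if k < spec.train_subjects else "test")
        for k, s in enumerate(order)
    }
    count_rng = _substream(spec.seed, 101)
    train_ids = sorted(s for s in range(spec.n_subjects) if split_of[s] == "train")
    test_ids = sorted(s for s in range(spec.n_subjects) if split_of[s] == "test")
    lo, hi = spec.images_per_subject
    counts = np.empty(spec.n_subjects, dtype=int)
    counts[train_ids] = _allocate_counts(
        count_rng, len(train_ids), lo, hi, spec.train_total_images
    )
    counts[test_ids] = _allocate_counts(
        count_rng, len(test_ids), lo, hi, spec.test_total_images
    )

    images: list[SyntheticImage] = []
    for s in range(spec.n_subjects):
        subject_id = f"s{s:03d}"
        proto = make_subject_prototype(spec.seed * 131071 + s, grid)
        srng = _substream(spec.seed, 200, s)
        n_img = int(counts[s])
        n_extra = n_img - spec.neutral_per_subject - spec.disguised_per_subject
        is_disguised = (
            [False] * spec.neutral_per_subject
            + [True] * spec.disguised_per_subject
            + [bool(srng.random() < 0.75) for _ in range(n_extra)]
        )
        for k, disguised in enumerate(is_disguised):
            image_id = f"{subject_id}_i{k:02d}"
            pixels = _render_image(proto, srng)
            face = NormalizedFace(
                pixels, subject_id=subject_id, is_neutral=not disguised,
                image_id=image_id,
            )
            coverage = np.zeros(pixels.shape)
            kinds: tuple[str, ...] = ()
            if disguised:
                n_acc = 1 + int(srng.random() < 0.3)
                chosen = srng.choice(len(pool), size=n_acc, replace=False)
                for a_idx in chosen:
                    acc = pool[int(a_idx)]
                    face, cov = apply_accessory(
                        face,
                        acc,
                        jitter_seed=int(srng.integers(2**31)),
                        jitter=spec.accessory_jitter,
                    )
                    coverage = np.maximum(coverage, cov)
                    kinds = kinds + (acc.kind,)
                face = NormalizedFace(
                    face.pixels, subject_id=subject_id, is_neutral=False,
                    image_id=image_id,
                )
            images.append(
                SyntheticImage(
                    face=face,
                    coverage=coverage,
                    annotation=annotate(coverage, grid),
                    accessories=kinds,
                    split=split_of[s],
                )
            )
    return SyntheticDataset(spec=spec, images=images)


def gallery_probe_split(
    dataset: SyntheticDataset,
    seed: int = 0,
    *,
    split: str = "test",
) -> tuple[list[str], list[str]]:
    """Per-subject gallery/probe partition of one split.

    For each subject: one neutral image plus four seeded-random others
    form the gallery; everything else is probe. Re-seeding supports the
    repeated random cross-validation trials of the evaluation protocol.
    """
    rng = _substream(seed, 300)
    by_subject: dict[str, list[SyntheticImage]] = {}
    for im in dataset.split_images(split):
        by_subject.setdefault(im.subject_id, []).append(im)
    gallery, probe = [], []
    for subject_id in sorted(by_subject):
        imgs = by_subject[subject_id]
        neutrals = [im for im in imgs if im.face.is_neutral]
        if len(imgs) < 5 or not neutrals:
            raise ValueError(
                f"subject {subject_id} needs >=5 images incl. a neutral one"
            )
        anchor = neutrals[int(rng.integers(len(neutrals)))]
        others = [im for im in imgs if im.image_id != anchor.image_id]
        pick = rng.choice(len(others), size=4, replace=False)
        chosen = {others[int(i)].image_id for i in pick} | {anchor.image_id}
        for im in imgs:
            (gallery if im.image_id in chosen else probe).append(im.image_id)
    return gallery, probe


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`.

    Coverage maps are not persisted; loaded images carry an all-zero
    coverage map and the annotations from the CSV grid.
    """
    from .faceio import read_image, read_manifest

    src = Path(in_dir)
    spec_dict = json.loads((src / "spec.json").read_text())
    grid = PatchGrid(**spec_dict.pop("grid"))
    spec_dict["images_per_subject"] = tuple(spec_dict["images_per_subject"])
    spec = SyntheticSpec(grid=grid, **spec_dict)
    manifest = read_manifest(src / "manifest.csv")
    ann = pd.read_csv(
        src / "annotations" / "patch_labels.csv", dtype={"image_id": str}
    )
    images = []
    for rec in manifest.itertuples():
        pixels = read_image(src / rec.path)
        sub = ann[ann["image_id"] == rec.image_id]
        grid_labels = np.full((grid.m, grid.n), BIOMETRIC, dtype=object)
        for a in sub.itertuples():
            grid_labels[a.row, a.col] = a.label
        images.append(
            SyntheticImage(
                face=NormalizedFace(
                    pixels,
                    subject_id=rec.subject_id,
                    is_neutral=bool(rec.is_neutral),
                    image_id=rec.image_id,
                ),
                coverage=np.zeros(pixels.shape),
                annotation=grid_labels.astype(str),
                accessories=(),
                split=rec.split,
            )
        )
    return SyntheticDataset(spec=spec, images=images)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write images/ (PGM), annotations/ (CSV grids), manifest.csv, spec.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    rows = []
    for im in dataset.images:
        write_image(out / "images" / f"{im.image_id}.pgm", im.face.pixels)
        for i in range(dataset.spec.grid.m):
            for j in range(dataset.spec.grid.n):
                rows.append(
                    {
                        "image_id": im.image_id,
                        "row": i,
                        "col": j,
                        "label": im.annotation[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(out / "annotations" / "patch_labels.csv", index=False)
    write_manifest(out / "manifest.csv", dataset.manifest())
    (out / "spec.json").write_text(dataset.spec.to_json())
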