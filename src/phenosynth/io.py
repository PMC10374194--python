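"""Readers/writers, run configuration, and the end-to-end pipeline.

Annotation dialects:

* COCO JSON — bbox ``[x, y, w, h]``, 0-based, half-open; polygon
  segmentation as flattened vertex lists; ``iscrowd=0``; ``area`` is the
  visible pixel count; detections carry a ``score`` field.
* Pascal VOC XML — bbox corners 1-based inclusive, so a COCO box
  ``(x, y, w, h)`` becomes ``xmin=x+1, ymin=y+1, xmax=x+w, ymax=y+h``.

Both conversions are exact inverses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image

from phenosynth.fixtures import Sprite
from phenosynth.pseudolabel import ScoredBox
from phenosynth.synthesis import SyntheticScene

logger = logging.getLogger("phenosynth")

__all__ = [
    "read_sprites",
    "write_sprite",
    "write_coco",
    "read_coco",
    "validate_coco",
    "write_voc",
    "read_voc",
    "coco_to_voc_bbox",
    "voc_to_coco_bbox",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Sprites
# ---------------------------------------------------------------------------


def write_sprite(sprite: Sprite, path: str) -> None:
    Image.fromarray(sprite.pixels, mode="RGBA").save(path)


def read_sprites(directory: str) -> List[Sprite]:
    """Load RGBA PNG sprites; species inferred from subdirectory names.

    Files without an alpha channel are skipped with a warning; zero valid
    sprites is an error.
    """
    root = Path(directory)
    if not root.is_dir():
        raise FileNotFoundError(f"sprite directory not found: {directory}")
    sprites: List[Sprite] = []
    for path in sorted(root.rglob("*.png")):
        try:
            img = Image.open(path)
        except Exception:
            warnings.warn(f"skipping non-image file {path}", stacklevel=2)
            continue
        if img.mode != "RGBA":
            warnings.warn(
                f"skipping {path}: no alpha channel (mode {img.mode})", stacklevel=2
            )
            continue
        species = path.parent.name if path.parent != root else path.stem
        sprites.append(
            Sprite(
                pixels=np.asarray(img, dtype=np.uint8),
                species_id=species,
                source="loaded",
            )
        )
    if not sprites:
        raise ValueError(f"no valid RGBA sprites found under {directory}")
    return sprites


# ---------------------------------------------------------------------------
# COCO
# ---------------------------------------------------------------------------


def write_coco(
    scenes: Sequence[SyntheticScene],
    image_files: Sequence[str],
    path: str,
    category: str = "fruit",
) -> dict:
    """Write scenes + annotations as a COCO JSON detection dataset."""
    images, annotations = [], []
    ann_id = 1
    seen_ids = set()
    for img_id, (scene, fname) in enumerate(zip(scenes, image_files), start=1):
        h, w = scene.image.shape[:2]
        images.append({"id": img_id, "file_name": fname, "width": w, "height": h})
        for ann in scene.annotations:
            if ann_id in seen_ids:
                raise ValueError(f"annotation id collision: {ann_id}")
            seen_ids.add(ann_id)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": 1,
                    "bbox": [float(v) for v in ann.bbox],
                    "segmentation": [ann.polygon] if ann.polygon else [],
                    "area": float(ann.area),
                    "iscrowd": 0,
                    "occlusion_ratio": float(ann.occlusion_ratio),
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": category}],
    }
    Path(path).write_text(json.dumps(doc))
    return doc


def read_coco(path: str) -> dict:
    doc = json.loads(Path(path).read_text())
    validate_coco(doc)
    return doc


def validate_coco(doc: dict) -> None:
    """Structural validation of a COCO detection document."""
    for key in ("images", "annotations", "categories"):
        if key not in doc or not isinstance(doc[key], list):
            raise ValueError(f"COCO document missing list field {key!r}")
    image_ids = {img["id"] for img in doc["images"]}
    if len(image_ids) != len(doc["images"]):
        raise ValueError("duplicate image ids")
    cat_ids = {c["id"] for c in doc["categories"]}
    ann_ids = set()
    for ann in doc["annotations"]:
        for key in ("id", "image_id", "category_id", "bbox", "area", "iscrowd"):
            if key not in ann:
                raise ValueError(f"annotation missing field {key!r}")
        if ann["id"] in ann_ids:
            raise ValueError(f"duplicate annotation id {ann['id']}")
        ann_ids.add(ann["id"])
        if ann["image_id"] not in image_ids:
            raise ValueError("annotation references unknown image")
        if ann["category_id"] not in cat_ids:
            raise ValueError("annotation references unknown category")
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate bbox {ann['bbox']}")


def coco_boxes_to_scored(doc: dict, default_score: float = 1.0) -> List[ScoredBox]:
    """COCO annotations -> ScoredBox list (score field optional)."""
    files = {img["id"]: img["file_name"] for img in doc["images"]}
    return [
        ScoredBox(
            image_ref=files[a["image_id"]],
            bbox=tuple(a["bbox"]),
            score=float(a.get("score", default_score)),
        )
        for a in doc["annotations"]
    ]


# ---------------------------------------------------------------------------
# Pascal VOC
# ---------------------------------------------------------------------------


def coco_to_voc_bbox(bbox: Sequence[float]) -> Tuple[int, int, int, int]:
    """COCO (x, y, w, h) 0-based half-open -> VOC 1-based inclusive corners."""
    x, y, w, h = bbox
    return (int(x) + 1, int(y) + 1, int(x + w), int(y + h))


def voc_to_coco_bbox(corners: Sequence[int]) -> Tuple[int, int, int, int]:
    xmin, ymin, xmax, ymax = corners
    return (xmin - 1, ymin - 1, xmax - xmin + 1, ymax - ymin + 1)


def write_voc(scene: SyntheticScene, image_file: str, path: str) -> None:
    """Write one scene's annotations as a Pascal VOC XML file."""
    h, w = scene.image.shape[:2]
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = image_file
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for ann in scene.annotations:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = ann.category
        ET.SubElement(obj, "difficult").text = "0"
        box = ET.SubElement(obj, "bndbox")
        xmin, ymin, xmax, ymax = coco_to_voc_bbox(ann.bbox)
        ET.SubElement(box, "xmin").text = str(xmin)
        ET.SubElement(box, "ymin").text = str(ymin)
        ET.SubElement(box, "xmax").text = str(xmax)
        ET.SubElement(box, "ymax").text = str(ymax)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_voc(path: str) -> List[Tuple[str, Tuple[int, int, int, int]]]:
    """Read a VOC XML file; returns (name, COCO bbox) per object."""
    root = ET.parse(path).getroot()
    out = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        box = obj.find("bndbox")
        corners = tuple(int(box.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax"))
        out.append((name, voc_to_coco_bbox(corners)))
    return out


# ---------------------------------------------------------------------------
# Run configuration and end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One-file configuration of the full demo pipeline."""

    seed: int = 0
    out_dir: str = "phenosynth_run"
    log_level: str = "INFO"
    # fixtures
    n_species: int = 3
    sprites_per_species: int = 8
    n_leaves: int = 10
    n_backgrounds: int = 3
    background_size: Tuple[int, int] = (512, 512)
    sprite_size: int = 256
    # features
    fourier_terms: int = 16
    contour_points: int = 128
    bin_width: float = 20.0
    n_patches: int = 16
    patch_size: int = 32
    shape_mode: str = "standard"
    # selection
    eps: Optional[float] = None
    min_samples: int = 4
    # synthesis
    n_scenes: int = 10
    min_fruits: int = 5
    max_fruits: int = 12
    max_occlusion: float = 0.5
    leaf_density: float = 1.0
    formats: Tuple[str, ...] = ("coco",)
    # pseudo-labeling
    rounds: int = 2
    grid_step: float = 0.01
    iou_threshold: float = 0.5

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not path.endswith(".json") else json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("background_size", "formats"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path: str) -> None:
        data = asdict(self)
        data["background_size"] = list(self.background_size)
        data["formats"] = list(self.formats)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Fixtures -> features -> source selection -> synthesis -> pseudo-labels.

    A demonstration run of the whole stack on procedurally generated
    inputs, with a manifest of seeds and output-file hashes for
    reproducibility auditing.
    """
    from phenosynth import commonality, fixtures, pseudolabel, synthesis
    from phenosynth._rng import stream, substream_seed

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1: fixtures")
    specs = fixtures.demo_species(config.n_species, seed=config.seed)
    sprites = fixtures.generate_species_collection(
        specs, config.sprites_per_species, size=config.sprite_size
    )
    leaves = [
        fixtures.generate_leaf_sprite(config.seed, i, size=config.sprite_size)
        for i in range(config.n_leaves)
    ]
    backgrounds = [
        fixtures.generate_background(
            config.background_size[0], config.background_size[1],
            seed=substream_seed(config.seed, 7, b),
        )[0]
        for b in range(config.n_backgrounds)
    ]

    logger.info("stage 2+3: features and source selection")
    selection = commonality.select_optimal_sources(
        sprites,
        eps=config.eps,
        min_samples=min(config.min_samples, config.n_species),
        level="dataset",
        seed=config.seed,
        out_json=str(out / "selection.json"),
        plot_path=str(out / "selection.png"),
        n_points=config.contour_points,
        n_terms=config.fourier_terms,
        mode=config.shape_mode,
        bin_width=config.bin_width,
        n_patches=config.n_patches,
        patch_size=config.patch_size,
    )

    logger.info("stage 4: scene synthesis")
    scene_cfg = synthesis.SceneConfig(
        n_fruits=(config.min_fruits, config.max_fruits),
        max_occlusion=config.max_occlusion,
        leaf_density=config.leaf_density,
        seed=substream_seed(config.seed, 8),
    )
    scene_dir = out / "scenes"
    manifest = synthesis.synthesize_dataset(
        sprites, leaves, backgrounds, scene_cfg, config.n_scenes,
        str(scene_dir), formats=config.formats,
    )

    logger.info("stage 5: pseudo-label self-learning (mock detector)")
    coco = read_coco(str(scene_dir / "annotations.json"))
    truth = coco_boxes_to_scored(coco)
    target_images = sorted({b.image_ref for b in truth})
    detector = fixtures.MockDetector(
        truth, image_size=(config.background_size[0], config.background_size[1])
    )
    result = pseudolabel.self_learning_loop(
        detector,
        synthetic_images=target_images,
        synthetic_labels=truth,
        target_images=target_images,
        rounds=config.rounds,
        grid_step=config.grid_step,
        seed=substream_seed(config.seed, 9),
    )

    logger.info("stage 6: evaluation")
    precision, recall, ap = pseudolabel.pr_curve_and_ap(
        result.labels, truth, iou_threshold=config.iou_threshold
    )
    bp, br = pseudolabel.balance_point(precision, recall)

    report = {
        "seed": config.seed,
        "selection": {
            "medoids": selection.clusters.medoids,
            "eps": selection.clusters.eps,
        },
        "synthesis": {
            "n_scenes": manifest["n_scenes_written"],
            "total_instances": manifest["total_instances"],
        },
        "pseudo_label": {
            "rounds": [
                {"round": r.round_index, "threshold": r.threshold,
                 "n_detections": r.n_detections, "n_retained": r.n_retained}
                for r in result.rounds
            ],
        },
        "evaluation": {
            "ap": ap,
            "balance_precision": bp,
            "balance_recall": br,
        },
        "hashes": {
            p.name: _sha256(p)
            for p in sorted(scene_dir.glob("*.png"))
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
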