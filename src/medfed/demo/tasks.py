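"""Reference implementations of the five benchmark pipeline tasks.

These are the functions behind the three demo cubes:

* data-preparation cube — :func:`task_prepare`, :func:`task_sanity_check`,
  :func:`task_statistics`;
* model cube — :func:`task_infer` (intensity thresholding, the simplest
  meaningful segmenter for bright-lesion imagery);
* metrics cube — :func:`task_evaluate` (overlap metrics per case plus
  aggregates).

All tasks are directory-to-directory/file transforms so they run equally
well in-process (unit tests) and under the cube runner (integration).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from ..errors import ValidationError
from ..hashing import sha256_file
from .metrics import METRIC_NAMES, overlap_metrics

PREPARED_MANIFEST = "prepared_manifest.json"
DEFAULT_TARGET = 64


def _load_grey(path: Path) -> np.ndarray:
    with Image.open(path) as img:
        if img.mode != "L":
            raise ValidationError(f"{path}: expected 8-bit greyscale, got {img.mode}")
        return np.asarray(img, dtype=np.uint8)


def _save_grey(array: np.ndarray, path: Path) -> None:
    Image.fromarray(array.astype(np.uint8), mode="L").save(path)


def _read_manifest(raw_dir: Path) -> list[dict[str, str]]:
    manifest = raw_dir / "manifest.csv"
    if not manifest.is_file():
        raise ValidationError(f"raw dataset has no manifest.csv under {raw_dir}")
    with open(manifest, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValidationError("manifest.csv lists no cases")
    return rows


def task_prepare(
    raw_dir: Path | str,
    labels_dir: Path | str,
    prepared_dir: Path | str,
    target_height: int = DEFAULT_TARGET,
    target_width: int = DEFAULT_TARGET,
) -> Path:
    """Transform a raw site dataset into the benchmark's canonical format.

    Each image is resized to the benchmark's fixed grid (bilinear; masks
    nearest-neighbour to stay binary), min-max rescaled per image to
    [0, 1] and re-quantized to 8 bits.  Writes ``data/*.png``,
    ``labels/*.png`` and a ``prepared_manifest.json`` carrying per-case
    digests so later stages can detect tampering.
    """
    raw_dir, labels_dir = Path(raw_dir), Path(labels_dir)
    prepared_dir = Path(prepared_dir)
    rows = _read_manifest(raw_dir)
    (prepared_dir / "data").mkdir(parents=True, exist_ok=True)
    (prepared_dir / "labels").mkdir(parents=True, exist_ok=True)

    cases = []
    for row in sorted(rows, key=lambda r: r["case_id"]):
        case_id = row["case_id"]
        image_path = raw_dir / row["image_path"]
        label_path = labels_dir / Path(row["label_path"]).name
        if not image_path.is_file():
            raise ValidationError(f"case {case_id}: image missing: {image_path}")
        if not label_path.is_file():
            raise ValidationError(f"case {case_id}: label missing: {label_path}")

        image = _load_grey(image_path)
        label = _load_grey(label_path)
        if image.shape != label.shape:
            raise ValidationError(f"case {case_id}: image/label shape mismatch")

        size = (target_width, target_height)  # PIL uses (W, H)
        with Image.fromarray(image, mode="L") as img:
            image = np.asarray(img.resize(size, Image.BILINEAR), dtype=np.float64)
        with Image.fromarray(label, mode="L") as lab:
            label = np.asarray(lab.resize(size, Image.NEAREST), dtype=np.uint8)

        lo, hi = image.min(), image.max()
        scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
        prepared = np.rint(scaled * 255.0).astype(np.uint8)
        # masks pass through untouched (nearest-neighbour preserves values);
        # a non-binary mask is the sanity check's finding, not ours to hide

        data_file = prepared_dir / "data" / f"{case_id}.png"
        label_file = prepared_dir / "labels" / f"{case_id}.png"
        _save_grey(prepared, data_file)
        _save_grey(label, label_file)
        cases.append(
            {
                "case_id": case_id,
                "data_digest": sha256_file(data_file),
                "label_digest": sha256_file(label_file),
            }
        )

    manifest = {
        "image_height": target_height,
        "image_width": target_width,
        "cases": cases,
    }
    (prepared_dir / PREPARED_MANIFEST).write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return prepared_dir


def _sanity_findings(prepared_dir: Path) -> list[str]:
    findings: list[str] = []
    manifest_path = prepared_dir / PREPARED_MANIFEST
    if not manifest_path.is_file():
        return [f"missing {PREPARED_MANIFEST}"]
    manifest = json.loads(manifest_path.read_text())
    shape = (manifest["image_height"], manifest["image_width"])

    for case in manifest["cases"]:
        case_id = case["case_id"]
        data_file = prepared_dir / "data" / f"{case_id}.png"
        label_file = prepared_dir / "labels" / f"{case_id}.png"
        if not data_file.is_file():
            findings.append(f"missing image: {case_id}")
            continue
        if not label_file.is_file():
            findings.append(f"missing mask: {case_id}")
            continue
        try:
            image = _load_grey(data_file)
            label = _load_grey(label_file)
        except ValidationError as exc:
            findings.append(str(exc))
            continue
        if image.shape != shape:
            findings.append(f"wrong image shape: {case_id} {image.shape}")
        if label.shape != shape:
            findings.append(f"wrong mask shape: {case_id} {label.shape}")
        if not np.isin(label, (0, 255)).all():
            findings.append(f"non-binary mask: {case_id}")
        if sha256_file(data_file) != case["data_digest"]:
            findings.append(f"image digest mismatch: {case_id}")
        if sha256_file(label_file) != case["label_digest"]:
            findings.append(f"mask digest mismatch: {case_id}")

    listed = {c["case_id"] for c in manifest["cases"]}
    on_disk = {p.stem for p in (prepared_dir / "data").glob("*.png")}
    for extra in sorted(on_disk - listed):
        findings.append(f"unmanifested image: {extra}")
    return findings


def task_sanity_check(prepared_dir: Path | str, report_path: Path | str) -> dict:
    """Integrity audit of a prepared dataset; never raises on bad data.

    Checks shapes, mask binarity, one-mask-per-image pairing, and per-case
    digests against the prepared manifest.  Writes (and returns) a report
    of the form ``{"pass": bool, "findings": [...]}``.
    """
    findings = _sanity_findings(Path(prepared_dir))
    report = {"pass": not findings, "findings": findings}
    Path(report_path).write_text(json.dumps(report, indent=1))
    return report


def task_statistics(prepared_dir: Path | str, statistics_path: Path | str) -> dict:
    """Aggregate statistics of a prepared dataset — never per-case values.

    Refuses to run on data that does not pass the sanity audit, so the
    published statistics always describe verified data.
    """
    prepared_dir = Path(prepared_dir)
    findings = _sanity_findings(prepared_dir)
    if findings:
        raise ValidationError(
            "statistics refused: sanity check fails: " + "; ".join(findings[:3])
        )
    manifest = json.loads((prepared_dir / PREPARED_MANIFEST).read_text())

    intensities = []
    foreground = []
    for case in manifest["cases"]:
        image = _load_grey(prepared_dir / "data" / f"{case['case_id']}.png")
        label = _load_grey(prepared_dir / "labels" / f"{case['case_id']}.png")
        intensities.append(image.astype(np.float64) / 255.0)
        foreground.append(float((label > 0).mean()))

    pixels = np.stack(intensities)
    stats = {
        "n_cases": len(manifest["cases"]),
        "image_height": manifest["image_height"],
        "image_width": manifest["image_width"],
        "mean_intensity": float(pixels.mean()),
        "sd_intensity": float(pixels.std()),
        "mean_foreground_fraction": float(np.mean(foreground)),
    }
    Path(statistics_path).write_text(json.dumps(stats, indent=1))
    return stats


def task_infer(
    prepared_dir: Path | str,
    predictions_dir: Path | str,
    threshold: float = 0.5,
) -> Path:
    """Reference segmenter: predict foreground where intensity > threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    prepared_dir = Path(prepared_dir)
    predictions_dir = Path(predictions_dir)
    predictions_dir.mkdir(parents=True, exist_ok=True)
    data_files = sorted((prepared_dir / "data").glob("*.png"))
    if not data_files:
        raise ValidationError(f"no prepared images under {prepared_dir}")
    for data_file in data_files:
        image = _load_grey(data_file).astype(np.float64) / 255.0
        mask = (image > threshold).astype(np.uint8) * 255
        _save_grey(mask, predictions_dir / data_file.name)
    return predictions_dir


def task_evaluate(
    predictions_dir: Path | str,
    labels_dir: Path | str,
    results_path: Path | str,
) -> dict:
    """Score predictions against prepared labels; write ``results.json``.

    The results file holds a per-case table and the arithmetic mean of
    each metric over cases; every value is finite by construction.
    """
    predictions_dir, labels_dir = Path(predictions_dir), Path(labels_dir)
    label_files = sorted(labels_dir.glob("*.png"))
    if not label_files:
        raise ValidationError(f"no labels under {labels_dir}")

    per_case = []
    for label_file in label_files:
        case_id = label_file.stem
        pred_file = predictions_dir / label_file.name
        if not pred_file.is_file():
            raise ValidationError(f"missing prediction for case {case_id}")
        truth = (_load_grey(label_file) > 127).astype(np.uint8)
        pred = _load_grey(pred_file)
        if not np.isin(pred, (0, 255)).all():
            raise ValidationError(f"non-binary prediction for case {case_id}")
        pred = (pred > 127).astype(np.uint8)
        metrics = overlap_metrics(pred, truth)
        per_case.append({"case_id": case_id, **metrics})

    aggregate = {
        name: float(np.mean([row[name] for row in per_case])) for name in METRIC_NAMES
    }
    results = {"n_cases": len(per_case), "aggregate": aggregate, "per_case": per_case}
    Path(results_path).write_text(json.dumps(results, indent=1))
    return results
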