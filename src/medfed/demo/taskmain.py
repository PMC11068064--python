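"""Dispatcher invoked by the demo cubes' ``run.py`` entrypoints.

Translates the runner's task argv convention into calls of the reference
task implementations.  Parameters come from the cube's digest-pinned
``parameters.yaml``; notably the model's ``threshold`` and an optional
``output_size`` override used to build a deliberately schema-incompatible
candidate model for compatibility-test exercises.
"""

from __future__ import annotations

import sys
from pathlib import Path

import yaml

from ..cubes import parse_task_args
from ..errors import MedfedError
from . import tasks


def _resize_predictions(predictions_dir: Path, size: int) -> None:
    # used only by the intentionally incompatible model variant
    from PIL import Image

    for path in sorted(predictions_dir.glob("*.png")):
        with Image.open(path) as img:
            img.resize((size, size), Image.NEAREST).save(path)


def main(argv: list[str]) -> int:
    task, inputs, outputs, params_path = parse_task_args(argv)
    params = {}
    if params_path:
        params = yaml.safe_load(Path(params_path).read_text()) or {}

    try:
        if task == "prepare":
            tasks.task_prepare(
                inputs["raw_data"],
                inputs["labels"],
                outputs["prepared_data"],
                target_height=int(params.get("target_height", tasks.DEFAULT_TARGET)),
                target_width=int(params.get("target_width", tasks.DEFAULT_TARGET)),
            )
        elif task == "sanity_check":
            tasks.task_sanity_check(inputs["prepared_data"], outputs["report"])
        elif task == "statistics":
            tasks.task_statistics(inputs["prepared_data"], outputs["statistics_file"])
        elif task == "infer":
            tasks.task_infer(
                inputs["prepared_data"],
                outputs["predictions"],
                threshold=float(params.get("threshold", 0.5)),
            )
            if "output_size" in params:
                _resize_predictions(
                    Path(outputs["predictions"]), int(params["output_size"])
                )
        elif task == "evaluate":
            tasks.task_evaluate(
                inputs["predictions"],
                inputs["prepared_labels"],
                outputs["results_file"],
            )
        else:
            print(f"unknown task {task!r}", file=sys.stderr)
            return 2
    except MedfedError as exc:
        print(f"{task} failed: {exc.message}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main(sys.argv[1:]))
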