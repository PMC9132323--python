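#!/usr/bin/env python
"""Generate every stimulus dataset (symbolic manifests) plus a small PNG
gallery of rendered examples.

Writes results/datasets/<experiment>_<variant>.csv (+ .meta.json sidecars)
and results/gallery/*.png.  Full datasets are 2000 training rows plus 500
rows per test condition; the gallery renders one image per condition for a
quick visual sanity check of the generator.
"""

from pathlib import Path

from PIL import Image

from shapebias import stimuli

OUT = Path("results")
DATASETS = [
    ("exp1", "a"), ("exp1", "b"), ("exp2", "a"), ("exp2", "b"),
    ("exp3", "a"), ("exp3", "b"), ("exp4", "a"), ("exp4", "b"),
    ("exp5_patch", "noshape"), ("exp5_segment", "noshape"),
    ("exp5_size", "noshape"), ("exp5_colour", "noshape"),
]
SEED = 0


def main() -> None:
    ds_dir = OUT / "datasets"
    gallery = OUT / "gallery"
    ds_dir.mkdir(parents=True, exist_ok=True)
    gallery.mkdir(parents=True, exist_ok=True)

    for experiment, variant in DATASETS:
        manifest = stimuli.generate_dataset(experiment, variant, seed=SEED)
        path = ds_dir / f"{experiment}_{variant}.csv"
        stimuli.write_manifest(manifest, path)
        n_shape = sum(s.shape_id is not None for s in manifest.train_rows)
        print(f"{experiment}_{variant}: {len(manifest.train_rows)} train rows "
              f"({n_shape} with shape), "
              f"{len(manifest.rows) - len(manifest.train_rows)} test rows "
              f"-> {path}")

        conditions = [stimuli.TRAIN] + [
            c for c in stimuli.TEST_CONDITIONS if manifest.subset(c)]
        for cond in conditions:
            spec = (manifest.train_rows if cond == stimuli.TRAIN
                    else manifest.subset(cond))[0]
            rendered = stimuli.render(spec, manifest.palette,
                                      manifest.templates)
            Image.fromarray(rendered.raster).save(
                gallery / f"{experiment}_{variant}_{cond}.png")

    print(f"\ngallery images under {gallery}/")


if __name__ == "__main__":
    main()
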