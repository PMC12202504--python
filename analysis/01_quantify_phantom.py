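"""Build synthetic aorta phantoms and run the ring-based PVAT quantification.

Verifies on a noiseless phantom that the pipeline recovers the constructed
shell attenuations exactly, then repeats with realistic CT noise.  Writes
per-phantom measurements to results/phantom_quantification.csv and the
NIfTI volumes to scratch/ (they are reproducible from the seed).
"""

import argparse
from pathlib import Path

import pandas as pd

from pvatscope import PhantomSpec, make_phantom, measure_pvat, save_mask, save_volume


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, noise in [("noiseless", 0.0), ("noise_sd_10HU", 10.0)]:
        spec = PhantomSpec(noise_sd_hu=noise, seed=args.seed)
        grid, mask, truth = make_phantom(spec)
        save_volume(grid, args.scratch / f"phantom_{label}_ct.nii.gz")
        save_mask(mask, args.scratch / f"phantom_{label}_aorta.nii.gz")
        m = measure_pvat(grid, mask)
        rows.append({
            "phantom": label,
            "configured_hu_close": spec.hu_fat_close,
            "configured_hu_distant": spec.hu_fat_distant,
            **m.as_dict(),
        })
        print(f"{label}: hu_close={m.hu_close:.3f} (built {spec.hu_fat_close}), "
              f"hu_distant={m.hu_distant:.3f} (built {spec.hu_fat_distant}), "
              f"hu_delta={m.hu_delta:.3f}, hu_ratio={m.hu_ratio:.4f}, "
              f"thickness {m.thick_close_mm:.2f}/{m.thick_distant_mm:.2f} mm, "
              f"QC pass={m.qc_pass}")

    out = args.out_dir / "phantom_quantification.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
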