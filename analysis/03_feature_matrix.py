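"""Vectorize spectrograms row-major into a 12 x 262,144 matrix; SNV rows.

Each 256 x 1024 spectrogram becomes one row (cell (i, j) at column
i*1024 + j).  Standard Normal Variate normalization then gives every
sample mean 0 / SD 1 across its 262,144 variables.
"""

import argparse
from pathlib import Path

import nmrmodal as nm
from nmrmodal.features import save_feature_matrix
from nmrmodal.fid import read_manifest


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", type=Path, default=Path("results/cohort/manifest.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/features"))
    args = ap.parse_args()

    df = read_manifest(args.manifest)
    specs = [nm.fid_to_spectrogram(nm.read_fid(p)) for p in df["path"]]
    raw = nm.assemble(specs)
    snv = nm.snv(raw)
    args.out.mkdir(parents=True, exist_ok=True)
    save_feature_matrix(raw, args.out / "raw.npz", args.out / "raw_sidecar.csv")
    save_feature_matrix(snv, args.out / "snv.npz", args.out / "snv_sidecar.csv")
    print(f"feature matrix: {snv.values.shape[0]} samples x "
          f"{snv.values.shape[1]} variables (grid {snv.grid_shape})")
    print(f"SNV rows: |mean| <= {abs(snv.values.mean(axis=1)).max():.2e}, "
          f"|sd - 1| <= {abs(snv.values.std(axis=1, ddof=1) - 1).max():.2e}")
    print(f"wrote raw + SNV matrices to {args.out}")


if __name__ == "__main__":
    main()
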