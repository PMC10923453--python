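"""STFT power spectrograms for every cohort FID; TIFF + ASCII export.

Each 16,384-point FID yields 511 frames of a 64-sample Hann-windowed,
hop-32, 1024-point DFT; the power matrix is cropped to the first 256
frames (the decaying FID's energy lives there), giving one 256 x 1024
time-frequency image per sample.
"""

import argparse
from pathlib import Path

import nmrmodal as nm
from nmrmodal.fid import read_manifest


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", type=Path, default=Path("results/cohort/manifest.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/spectrograms"))
    args = ap.parse_args()

    df = read_manifest(args.manifest)
    args.out.mkdir(parents=True, exist_ok=True)
    params = nm.STFTParams()
    for _, row in df.iterrows():
        rec = nm.read_fid(row["path"])
        full = nm.stft(rec, params)
        sp = nm.spectrogram(full)
        nm.export_spectrogram(
            sp,
            image_path=args.out / f"{rec.sample_id}.tiff",
            ascii_path=args.out / f"{rec.sample_id}.txt",
        )
        print(f"{rec.sample_id}: {full.n_frames} frames computed -> "
              f"kept {sp.shape[0]} x {sp.shape[1]} "
              f"(peak power {sp.power.max():.3e})")
    print(f"wrote {2 * len(df)} files to {args.out}")


if __name__ == "__main__":
    main()
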