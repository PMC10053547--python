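"""Generate the synthetic study bundle every later stage consumes.

Writes, under results/synthetic/:
  surveys/       70 pen-month quadrat surveys (clustered truth)
  surveys_null/  70 surveys under the Poisson (random) null
  tanks/         18 overnight tank patterns (25/20/10 animals x 6 replicates,
                 clustered) plus a 13-frame time-lapse-like series of one
                 40-animal tank
  assays.csv     synthetic Y-tube outcomes for the stimulus panel + control
  library.csv / profiles.csv   saponin library and generated profile set
"""

from pathlib import Path

from scabra import io as sio
from scabra import synthetic as syn
from scabra.pipeline import default_assay_records
from scabra.saponins import load_reference_library

SEED = 7
OUT = Path("results/synthetic")


def main() -> None:
    for sub in ("surveys", "surveys_null", "tanks"):
        (OUT / sub).mkdir(parents=True, exist_ok=True)

    for clustered, sub in ((True, "surveys"), (False, "surveys_null")):
        for sv in syn.gen_survey_campaign(clustered=clustered, seed=SEED):
            sio.write_survey(OUT / sub / f"{sv.pen_id}_{sv.month}.csv", sv)

    tanks = syn.gen_aquarium_experiments(clustered=True, seed=SEED + 1)
    for i, p in enumerate(tanks, start=1):
        sio.write_pattern(OUT / "tanks" / f"overnight_{i:02d}.csv", f"overnight_{i:02d}", p)
    # time-lapse-like frames: random at first, then three tight groups
    for t in range(13):
        if t < 2:
            pat = syn.gen_csr_pattern(40, syn.TANK, (SEED + 2, t))
        else:
            pat = syn.gen_clustered_tank(40, (SEED + 2, t), spread=2.0 + 0.5 * max(0, 6 - t))
        sio.write_pattern(OUT / "tanks" / f"frame_t{t:02d}.csv", f"frame_t{t:02d}", pat)

    records, control = default_assay_records(SEED + 3)
    sio.write_assays(OUT / "assays.csv", records + [control], {control.stimulus})

    library = load_reference_library()
    profiles = syn.gen_profiles(
        library, n_attractive=3, n_nonattractive=2,
        marker_mzs=[905.4, 889.4], p_background=0.3, seed=SEED + 4,
    )
    sio.write_library(OUT / "library.csv", library)
    sio.write_profiles(OUT / "profiles.csv", profiles)

    print(f"wrote synthetic bundle (seed {SEED}) under {OUT}/")
    print(f"  surveys: 70 clustered + 70 null; tanks: {len(tanks)} overnight + 13 frames")


if __name__ == "__main__":
    main()
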