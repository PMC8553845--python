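#!/usr/bin/env python
"""Simulate a goniometer scan of the synthetic honeybee-forager eye.

Builds the preset eye model, scans it noiselessly over the default grid
(latitude -40..+40 deg, longitude -10..+60 deg, 10-deg steps) and writes the
pseudopupil-centre observation table that the later stages consume.
"""

from pathlib import Path

from pseudopupil.interface import write_observations
from pseudopupil.synthetic_eye import honeybee_eye, scan

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    eye = honeybee_eye(seed=0)
    observations = scan(eye)
    out = RESULTS / "observations.tsv"
    write_observations(observations, out)

    lats = sorted({o.pose.latitude_deg for o in observations})
    lons = sorted({o.pose.longitude_deg for o in observations})
    print(f"synthetic honeybee eye: facet pitch {eye.pitch_um} um, "
          f"lattice extent u={eye.extent[0]}, v={eye.extent[1]}")
    print(f"scanned {len(lats)} latitudes x {len(lons)} longitudes = "
          f"{len(observations)} poses -> {out}")
    frontal = next(o for o in observations if o.pose == (0.0, 0.0))
    print(f"frontal pose centres at lattice ({frontal.centre.u:.3f}, "
          f"{frontal.centre.v:.3f}) — the origin facet, as constructed")


if __name__ == "__main__":
    main()
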