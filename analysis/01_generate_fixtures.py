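"""Generate the synthetic time-resolved SAXS series for every condition.

Emits one fixture per gelation condition (two independent replicates at
pH 7.0, mirroring the duplicated measurement) under results/fixtures/:
30 frames at the 5 s acquisition cadence plus the 10 h equilibrated
full-gel frame, a matched buffer profile, and the generating trajectory
for later recovery scoring.
"""

from pathlib import Path

from clexsaxs.synthetic import write_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"

RUNS = [
    ("pH7.0-rep1", "pH7.0", 101),
    ("pH7.0-rep2", "pH7.0", 102),
    ("pH7.4", "pH7.4", 103),
    ("pH8.0", "pH8.0", 104),
    ("pH8.0-alt", "pH8.0-alt", 105),
    ("GDL-control", "GDL-control", 106),
]


def main() -> None:
    for label, preset, seed in RUNS:
        manifest = write_fixture(OUT / label, scenario_name=preset, seed=seed)
        print(f"{label}: wrote {manifest}")


if __name__ == "__main__":
    main()
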