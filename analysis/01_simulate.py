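#!/usr/bin/env python
"""Generate the synthetic sessions the downstream analyses run on.

Writes four seeded sessions under results/sessions/: the main planted
sequence session (the recovery conditions: 200 units, 20 trials per target,
100 ms peak jitter), a default-condition session with realistic jitter and
error trials, a persistent-mode session (the classical delayed-response
contrast), and an unstructured control.
"""

import argparse
from pathlib import Path

from nascode.session_io import validate_session, write_session
from nascode.synth import SynthConfig, generate_session

SESSIONS = {
    "recovery": dict(n_units=200, n_trials_per_target=20, peak_jitter_sd_s=0.1,
                     incorrect_frac=0.0),
    "default": dict(),
    "persistent": dict(n_units=100, n_trials_per_target=12, mode="persistent",
                       incorrect_frac=0.0),
    "unstructured": dict(n_units=50, n_trials_per_target=8, mode="unstructured",
                         incorrect_frac=0.0),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for i, (name, kw) in enumerate(SESSIONS.items()):
        cfg = SynthConfig(seed=args.seed + i, **kw)
        session = generate_session(cfg)
        violations = validate_session(session)
        assert not violations, violations
        dest = args.outdir / "sessions" / name
        write_session(session, dest)
        print(f"{name}: {len(session.units)} units, {len(session.trials)} trials, "
              f"{len(session.spikes)} spikes, 0 validation issues -> {dest}")


if __name__ == "__main__":
    main()
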