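"""Regenerate the packaged fingerprint targets from synthetic ensembles.

Usage: python scripts/make_targets.py   (writes src/natrace/data/targets.json)
"""
import json
from pathlib import Path

from natrace.synthetic import build_default_targets

targets = build_default_targets(seed=0, n_members=50, amplitude=0.25)
out = Path(__file__).resolve().parents[1] / "src" / "natrace" / "data" / "targets.json"
out.write_text(json.dumps({k: t.to_dict() for k, t in targets.items()}, indent=1) + "\n")
for name, t in targets.items():
    print(f"{name}: n={t.n} high={t.high_names}")
print(f"wrote {out}")
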