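"""Ensures this directory is importable (for helpers.py) under any rootdir."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
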