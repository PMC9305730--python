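"""Make the in-repo package importable when running scripts without install."""

import sys
from pathlib import Path

src = Path(__file__).resolve().parents[1] / "src"
if str(src) not in sys.path:
    sys.path.insert(0, str(src))

add_src_to_path = True
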