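"""Minimal EDF byte-writer for exercising the EDF reader in tests.

Builds a standards-conformant European Data Format file (ASCII header +
16-bit little-endian samples) from a channels x samples float array.  This
exists only so EDF fixtures can be synthesized at test time; it is not part
of the package surface.
"""

import numpy as np


def write_minimal_edf(path, data, fs, labels, phys_range=200.0):
    data = np.asarray(data, dtype=float)
    n_ch, n_samples = data.shape
    assert n_samples % int(fs) == 0, "use whole seconds for the fixture"
    n_records = n_samples // int(fs)
    spr = int(fs)  # one-second data records

    def f(text, width):
        return f"{text:<{width}}"[:width].encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2020", 80),
        f("01.01.20", 8), f("00.00.00", 8),
        f(str(256 + 256 * n_ch), 8), f("", 44),
        f(str(n_records), 8), f("1", 8), f(str(n_ch), 4),
    ])
    dig_max, dig_min = 32767, -32768
    sig = b"".join([
        b"".join(f(lbl, 16) for lbl in labels),
        b"".join(f("", 80) for _ in labels),
        b"".join(f("uV", 8) for _ in labels),
        b"".join(f(str(-phys_range), 8) for _ in labels),
        b"".join(f(str(phys_range), 8) for _ in labels),
        b"".join(f(str(dig_min), 8) for _ in labels),
        b"".join(f(str(dig_max), 8) for _ in labels),
        b"".join(f("", 80) for _ in labels),
        b"".join(f(str(spr), 8) for _ in labels),
        b"".join(f("", 32) for _ in labels),
    ])
    scale = dig_max / phys_range
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")
    records = b"".join(
        digital[:, r * spr:(r + 1) * spr].tobytes()
        for r in range(n_records)
    )
    with open(path, "wb") as fh:
        fh.write(header + sig + records)
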