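import numpy as np

from mwmtsa import Trajectory


def straight_trajectory(length_cm: float = 1000.0, n: int = 1001,
                        speed: float = 25.0, y: float = 0.0) -> Trajectory:
    """Straight east-bound path of exactly the requested arc length.

    Segmentation and arc-length code never consult the arena, so the path
    may extend beyond the default pool.
    """
    xs = np.linspace(0.0, length_cm, n)
    t = xs / speed
    return Trajectory("straight", "test", 1, 1, t,
                      np.column_stack([xs, np.full(n, y)]))
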