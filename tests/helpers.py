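"""Independent oracles used by the unit and acceptance suites."""

from cyanoarch.genome_core import Interval


def walking_gap(a: Interval, b: Interval, length: int, topology: str) -> int:
    """Base-walking oracle for the minimum gap between two intervals.

    Counts intervening positions one base at a time along each arc,
    independently of the modular arithmetic used by the implementation.
    """
    pos_a = set(range(a.start, a.end))
    pos_b = set(range(b.start, b.end))
    if pos_a & pos_b:
        return 0

    def walk(start: int, stop: int) -> int:
        count = 0
        p = start % length
        stop %= length
        while p != stop:
            count += 1
            p = (p + 1) % length
            if count > length:  # safety
                raise RuntimeError("walk did not terminate")
        return count

    if topology == "linear":
        if b.start >= a.end:
            return b.start - a.end
        return a.start - b.end
    return min(walk(a.end, b.start), walk(b.end, a.start))
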