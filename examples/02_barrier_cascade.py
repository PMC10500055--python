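"""The sequential barrier cascade and total isolation.

Re-cascades the published per-barrier indices of two directions: one
with complete sexual isolation (every later barrier contributes
nothing) and one partially isolated direction where several barriers
share the work.
"""

from crossri import datasets, ladder_from_ri_values

for direction in (("BIR", "SAT"), ("CAN", "STU")):
    values = datasets.published_barrier_ri(direction)
    ladder = ladder_from_ri_values(values, direction=direction)
    print(f"\n{direction[0]} female x {direction[1]} male")
    for est, ac in zip(ladder.estimates, ladder.AC):
        print(f"  {est.barrier.value:<40s} RI={est.RI:+.3f}  AC={ac:+.4f}")
    for skipped in ladder.skipped:
        print(f"  {skipped.value:<40s} not studied (skipped)")
    print(f"  total isolation T = {ladder.T:.4f}")

print("\nAC_n = RI_n x (1 - sum of earlier ACs): a barrier only removes "
      "gene flow that earlier barriers let through, so a complete first "
      "barrier forces T = 1 regardless of the rest.")
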