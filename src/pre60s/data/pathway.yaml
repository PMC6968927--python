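# Cytoplasmic pre-60S maturation pathway as an event-dependency graph.
#
# Events are release(factor), recruit(factor) or load(r-protein); an event
# fires only once all events in `requires` have fired. `blockable` names the
# perturbation handle that can disable the event (a dominant-negative enzyme).
# Events marked `inferred: true` encode observed accumulation/recruitment
# behaviour whose mechanism is speculative; they are excluded from the core
# factor set used for hard cross-checks.
#
# Edit freely: the graph is data, not code.

preloaded:
  # assembly/export factors already on the particle when it reaches the cytoplasm
  - Rlp24
  - Bud20
  - Nog1
  - Arx1
  - Mrt4
  - Nsa2
  - Tif6
  - Nmd3
  - Mex67
  - Ecm1
  - Tma16

core_factors:
  # factors whose dependency placement is structurally established; used for
  # exact-set comparisons against trapped-particle compositions
  - Rlp24
  - Bud20
  - Nog1
  - Mrt4
  - Nmd3
  - Tif6
  - Rei1
  - Yvh1

perturbations:
  Drg1DN: [release(Rlp24)]     # dominant-negative Drg1 ATPase (or diazaborine)
  Nog1DN: [release(Nog1)]      # dominant-negative Nog1 G-domain (G223A)

events:
  # --- initiation: Drg1 extracts Rlp24, coupled Bud20 release ---
  - name: release(Rlp24)
    factor: Rlp24
    kind: release
    requires: []
    blockable: Drg1
  - name: release(Bud20)
    factor: Bud20
    kind: release
    requires: [release(Rlp24)]

  # --- exit-tunnel branch: Rei1 probing, Arx1 release, Reh1 succession ---
  - name: recruit(Rei1)
    factor: Rei1
    kind: recruit
    requires: [release(Rlp24)]
  - name: release(Arx1)
    factor: Arx1
    kind: release
    requires: [recruit(Rei1)]
  - name: release(Rei1)
    factor: Rei1
    kind: release
    requires: [recruit(Rei1), release(Arx1)]
  - name: recruit(Reh1)
    factor: Reh1
    kind: recruit
    requires: [release(Rei1)]

  # --- Nog1 eviction gates the stalk branch and PTC maturation ---
  - name: release(Nog1)
    factor: Nog1
    kind: release
    requires: [release(Rlp24)]
    blockable: Nog1-G
  - name: recruit(Yvh1)
    factor: Yvh1
    kind: recruit
    requires: [release(Nog1)]
  - name: release(Mrt4)
    factor: Mrt4
    kind: release
    requires: [recruit(Yvh1)]
  - name: load(uL16)
    factor: uL16
    kind: load
    requires: [release(Nog1)]
  - name: load(eL40)
    factor: eL40
    kind: load
    requires: [release(Nog1)]
  - name: release(Nsa2)
    factor: Nsa2
    kind: release
    requires: [release(Nog1)]
    inferred: true            # precedence established, mechanism unknown

  # --- convergence: uL16 accommodation, Nmd3 then Tif6/Reh1 release ---
  - name: release(Nmd3)
    factor: Nmd3
    kind: release
    requires: [load(uL16)]
  - name: release(Tif6)
    factor: Tif6
    kind: release
    requires: [release(Nmd3)]
  - name: release(Reh1)
    factor: Reh1
    kind: release
    requires: [recruit(Reh1), release(Nmd3)]

  # --- observed co-trapping with speculative placement ---
  - name: recruit(Sqt1)
    factor: Sqt1
    kind: recruit
    requires: []
    inferred: true            # uL16 chaperone docks before the block
  - name: release(Sqt1)
    factor: Sqt1
    kind: release
    requires: [load(uL16)]
    inferred: true
  - name: release(Tma16)
    factor: Tma16
    kind: release
    requires: [release(Nog1)]
    inferred: true
  - name: release(Mex67)
    factor: Mex67
    kind: release
    requires: [release(Nog1)]
    inferred: true
  - name: release(Ecm1)
    factor: Ecm1
    kind: release
    requires: [release(Nog1)]
    inferred: true
  - name: recruit(Arb1)
    factor: Arb1
    kind: recruit
    requires: [release(Nmd3)]
    inferred: true
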