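# Cellular cholesterol homeostasis reaction network.
# 22 biochemical processes; the PCSK9-mediated LDLR degradation chain
# contributes two irreversible reactions (k14, k16), giving 23 reactions.
@species Sci C Sr Sh R Cf Cp Ce E HR H Sp P CL
@chemostat CL
0 -> Sci ; rate=mu                     # constitutive SREBP/Scap/Insig production in the ER
Sci -> Sci + Sr + Sh + Sp ; rate=k1    # release of the three SREBP transcription factors
Sr -> Sr + R ; rate=p1                 # LDLR gene expression
Sh -> Sh + HR ; rate=p2                # HMGCR gene expression
Sp -> Sp + P ; rate=p3                 # PCSK9 gene expression
Sr -> 0 ; rate=k2                      # degradation of the LDLR transcription factor
Sh -> 0 ; rate=k10                     # degradation of the HMGCR transcription factor
Sp -> 0 ; rate=k13                     # degradation of the PCSK9 transcription factor
R + CL -> R + Cf ; rate=k3             # receptor-mediated uptake and release of LDL cholesterol
R -> 0 ; rate=k11                      # Idol-mediated ubiquitylation and degradation of LDLR
P + R -> P ; rate=k14                  # PCSK9-mediated degradation of LDLR
P -> 0 ; rate=k16                      # lysosomal degradation of PCSK9
Cf -> Cp ; rate=k4                     # free LDL cholesterol joins the PM pool
Cp <-> Ce ; fwd=k5, rev=k6             # cholesterol flux between PM and ER membrane
Ce -> E ; rate=k7                      # cholesterol esterification
E -> Ce ; rate=k8                      # cholesterol-ester hydrolysis
0 -> H ; rate=alpha                    # constitutive HMG-CoA production
H + HR -> HR + Ce ; rate=k9            # HMGCR-catalysed cholesterol biosynthesis
Ce + HR -> Ce ; rate=k15               # sterol-induced degradation of HMGCR
Ce -> Ce + C ; rate=theta              # active cholesterol released into the ER lumen
Sci + C -> 0 ; rate=eta                # SREBP/Scap/Insig/cholesterol complex retention in the ER
Ce -> 0 ; rate=k12                     # ABCA1-mediated cholesterol efflux
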