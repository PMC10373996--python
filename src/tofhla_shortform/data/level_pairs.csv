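true_level,predicted_level
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,inadequate
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
inadequate,marginal
marginal,inadequate
marginal,inadequate
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,marginal
marginal,adequate
marginal,adequate
marginal,adequate
marginal,adequate
marginal,adequate
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,marginal
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
adequate,adequate
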