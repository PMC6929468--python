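1AY7_A
1B6C_A
1B7Y_B
1AZS_B
1B7Y_A
1AVG_H
1AZS_C
1B6C_B
1UDI_E
1UGH_E
1ZBD_A
1UEA_A
1UUZ_A
1TCO_A
3TGI_I
1WQ1_G
1HLU_P
1IRA_Y
1KKL_A
1HWH_B
1JSU_C
1HLU_A
1IRA_X
1ITB_A
1BDJ_B
1BMQ_A
1BRB_I
1BGX_T
1BP3_A
1BDJ_A
1BI7_A
1BMQ_B
1QBK_B
1SMP_A
7CEI_A
1QBK_C
1STF_E
1PYT_B
1SGP_E
1SMP_I
1FLT_Y
1GLA_F
1HJA_C
1GFW_A
4SGB_I
1FLT_V
1GFW_B
1GLA_G
1ABR_A
1AHW_C
1ATN_D
1ABR_B
1AK4_D
1A4Y_A
1ACB_I
1AK4_A
1BVK_A
1CA0_B
1D4V_B
1BVK_C
1D4V_A
1BRS_A
1BVN_P
1CXZ_B
2KAI_B
2SIC_I
3SGB_I
2PCC_A
2TEC_E
1ZBD_B
2PCC_B
2SNI_I
1DAN_U
1E9H_B
1FAP_B
1DFJ_E
1ETH_A
1DAN_L
1E96_A
1EFU_B
1L0Y_A
1NOC_B
1PYT_A
1L0Y_B
1PDK_B
1KKL_H
1MAH_A
1PDK_A
1GUA_B
1STF_I
1UEA_B
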