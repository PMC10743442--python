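>synthetic_cterm_ig_01
FVKDVMSDEGQCTECKYNTHALPWVTTEGNPFYPDMMDE-TVNVSSLAAKFIP-VMQEATFELKGKYNKLKFRPQIECCRGAQKDLTKKRVDAHLRDKQN
>synthetic_cterm_ig_02
FQSLIFGGLGTSVDSSRQHDIRLWQWGWIHIWWGINDDNEKDKGECKQMLSGPMGILDWKPRP--SYSSQNPVWYSNYCPDCRGWMWKQAVHCHHDMIIS
>synthetic_cterm_ig_03
GAAQNNWDAGPRSMHSCADVQG-WNCKTPLQFPM-DGDCEKQVYHTGVPG-FPSCPPEMPSWM-LHYYNMLPAPCWIGCPWRFFPCW-DFGISHNAAMAS
>synthetic_cterm_ig_04
ASGDPFRSPGALEVRDGGERPGIWVFTKNDPYVRYWADNMMWTGSCPFWVV-PFRI-KTQNCTQDHYCSPHRCGYGYKCKPDYTKWQQVTATLHCRQVCS
>synthetic_cterm_ig_05
SWDSTHQ-EGPKWWVGRKIAPCTWECQPTEVYYEDVYDMKYAEFWRYDQSEKPNVKMARCP-MFPFYEEIHDTMMMVRCYSCLLLHSMHA-MYHRACACE
>synthetic_cterm_ig_06
KC-GKFIWVGNIEFMWSTNYPTCWCKQHHCPETQN-CDITRVDWAV-GSNVRPKKHK-MMDKEMQHYFRPCSWWFASVCCTWTDCMIYNMEPQHFEILTV
>synthetic_cterm_ig_07
RSVQVEMEIGCTGIAPFSGY-RWWEKFPAHTATWWYEDSDNEPAAPVC-HWNPVHQEPPDGFMQ-VYMRMWDPGNVSNCACCDQCRLRM-FSMHHYNTKG
>synthetic_cterm_ig_08
NN-WPPNFGGSLKEKRRFIALVGWSVSWVQWEKH-SEDPFLDFKPKAWTSSYPTEICDYIHMGDTAYWWAY-LDVPFVCNPYIESFDLN-KDGHGPWWHR
>synthetic_cterm_ig_09
YKDETGHCPGL-WVQPGLAVCEVWKRKWMFQ-KI-FTDDERQRNMDFNDFGWPVI-DHSVYKCMVYYRMIFGFSN-HFCNGGKHSTQAPQDAWHGSYELS
>synthetic_cterm_ig_10
-EHSSNGNNGTTDQERGMVADRLWYKPESRMSFRHRDDVIWWCQIFTTTMESPSTYPGMGVCQRIQYMCITSAFGGQICIHRIFW-MYK-YTEHV-TFGN
>synthetic_cterm_ig_11
CVKCDLRLQGLGYPDWHLYDGPCWDHVLIKMDDYV-KD-HYNCVH-GPRYSSPALSADQYSCFEQMYTRKCALNEH-ECRCQAKDFSHDAPRQHT-GECM
>synthetic_cterm_ig_12
YVMWGGEEWGQKDNMPEFW-ASHWYFWGRSNWELDCKDHARD-KGVQCDFRKPRWRIKAYKYVNPKYEYYCQINDAYQCQWWVQMQGFQSGFIHMKDFY-
>synthetic_cterm_ig_13
KKPVIQISVGHNVVETVQ-WESSWKAIGMDIEPTPGMDI-PSIAERIMHDVQPCLGHFWACVMPANYCTFILYSFKGMCVTAIYCC-TNGHDCHSRTSTL
>synthetic_cterm_ig_14
EDPIRRLRVGSC-LKTDYNPYQAWIWAQKPQPIGACAD-QASPSGTMVPQMPP-IWAACCDMCMSEYLQESCSLQCTFCGKPGLYTPSNWWGGHCELLLW
>synthetic_cterm_ig_15
RTSIRCIGMGQGTDAGEQRVVEHWELGHHFWHCICTEDYWKNVSHSQPH-E-PFGIAKFYYTPGQHYMCGPWI-QMRSCEYMEMFCLYERFPHHHWPAHN
>synthetic_cterm_ig_16
ADMSQPNCCGSYMLIALWQNIKMWQ-MNRRNGPDMNCDDRPDGSPIIYDHPTPTIFMP-CPPMAWGYM-IYVWDANPTCFMCSSHPRKIEEYRHIHMEHE
>synthetic_cterm_ig_17
-SWLGPFGMGEWYQLTTACQPMAWDFKEIWYRNCKKFDMNHVTAGKWCDPYWPWKPWVGA-FQCNLYWERDHEYTPEPCWTR-WAHQEQLLPYHSRFPWQ
>synthetic_cterm_ig_18
EDAMPTTRSGHLGVSIWRAMC-GWPD-SSSRKCSWDADRLPYYI-TFNTAWAPEHKWIGWGITEVMYFTGMYCY-VFQCDALCSLSWTRFWWHH-NHGCR
>synthetic_cterm_ig_19
RRN--LRMFGFQWKFNKRSFEFTWIFHDCVMYDKTLPDGQ-DG-PVWLGQ-PPWYFKHHRQGQMTNYMAIEQKHHKHCCWPEGHGANVRLALKHFVYHGM
>synthetic_cterm_ig_20
LREYCWKPFGPRTWNYDNKWVVWWDWYQTEDIRCWVDDDMVDMSYSDWVSEPPAHRGAGVDMRMSRYGHIDNDFAHVHCWWFKFIQCY-INHTHTLWPLG
>synthetic_cterm_ig_21
MRQNHYSMQGQRNYVWSSQDCCEWPN-KGWFI-FIGIDPRQWQKYCWIIDHPPYMIKMPPVSYS-FYNERMHATRTKVCGNRWKQYWGN-SCEHFLLRIM
>synthetic_cterm_ig_22
SYRQDHDLTGTQ-FWGQFGWKAKWLEMCQHT-AFLPMDIYAKMSKHPYEFDAPFSMEYSKDR-LDGYEVDSLLFNEYWCVELETSPRLRIIGMHVYTWDQ
>synthetic_cterm_ig_23
AIWEDTHDFGIKYKCTHADNQ-EWVHNGDQKHYRQDRDW-TTSFHEIYLRFAPIQLAWSSSREGYMYEGLGLYVAPWKCKRADCQLICWNIFMHLPYLKM
>synthetic_cterm_ig_24
KPCFHMYSAGETTIDYEKPVVFFWQQLLFYSDC-HCIDKPEKEMWLDNKDFHPDWGQIGFEKWKASYMGRWMMLRRYECIESYAEVKIMVAKEHNISYWV
>synthetic_cterm_ig_25
MARHFPVYHGQKAQYKALF-THAWMKAKCRHSQTICCDMT-RWDQKAQRGDCPMSYENTEQC-GSNYGYKWYVEPLHYCVWWPTFQFLDHILQHPVV-QH
>synthetic_cterm_ig_26
QYYISYWDFGDEGNTIEWWTVYGWMDFNRNYATL-DTD-YPEVEPL-QVVMRPYRFVLEKQADSQPYPFYDKFQKPPYCEPCCGVQVYNWRLYHFSW-CM
>synthetic_cterm_ig_27
MFSHFRLKMGTY-RTKLPFRGSPWWDRGILGYTF-SQD-MWFLKMVPPMRYYPDYSRCPPALAHKPYLGPNCSLFMFNCYEFCEEKQRRTF-VHQCFVTN
>synthetic_cterm_ig_28
TTQVWIKCVGDKFDTTWMPKCTFWCFKCWDPHEEYPRDVCVCGYNSHWEASYPNIRGRILMY-AHIYPICIN-VVDHKCMTVDYSQDH-YRHVHQIIHAQ
>synthetic_cterm_ig_29
NSQTDEIEGGNWTDCCMHCTDQFWWCMCDFLPLTQRWDWTVPIIQT-CRVVCPDGQYRCPTYEF-HYKRQGPGMGT-QCCMIYL-AISVCCADHCYHMAY
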